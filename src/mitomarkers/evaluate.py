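"""Rough annotation from marker occurrences and its comparison to a reference.

Overlapping marker occurrences with identical target gene and strand are
merged into predicted fragments.  Each fragment is paired with the reference
annotation sharing the most positions with it, provided the shared part is
at least 25% of the fragment's length, and the pair is classified *equal*
(same gene and strand), *Δ±* (same gene, other strand) or *different*
(another gene); unpaired fragments are false positives and reference
annotations never chosen as a partner are false negatives.  Reports are
broken down by mitochondrial gene class (protein / rRNA / tRNA / control
region) using a configurable name-pattern table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .classify import classified_occurrences
from .gst import TruncatedGST
from .model import (ClassifiedOccurrence, GeneAnnotation, GeneKey, Marker,
                    PredictedFragment)

#: gene class name -> regex over lower-cased gene names (first match wins)
DEFAULT_GENE_CLASSES: Sequence[Tuple[str, str]] = (
    ("protein", r"^(nad\d+l?|nd\d+l?|cox?\d+|cob|cytb|atp\d+)$"),
    ("rRNA", r"^(rrn[sl]|rns|rnl|12s.*|16s.*)$"),
    ("tRNA", r"^trn.*$"),
    ("control region", r"^(oh|ol|cr|d.?loop|control.*)$"),
)


def gene_class(
    gene: str, classes: Sequence[Tuple[str, str]] = DEFAULT_GENE_CLASSES
) -> str:
    name = gene.lower()
    for cls, pattern in classes:
        if re.match(pattern, name):
            return cls
    return "other"


def build_rough_annotation(
    occurrences: Iterable[ClassifiedOccurrence], merge_gap: int = 0
) -> List[PredictedFragment]:
    """Merge overlapping same-target occurrences into maximal fragments.

    Strict positional overlap (at least one shared position) is required by
    default; ``merge_gap`` > 0 additionally merges intervals separated by up
    to that many positions (``merge_gap=1`` merges book-ended intervals).
    """
    groups: Dict[Tuple[str, str, str], List[Tuple[int, int]]] = {}
    for occ in occurrences:
        groups.setdefault((occ.source_id, occ.gene, occ.strand), []).append(
            (occ.start, occ.end)
        )
    fragments: List[PredictedFragment] = []
    for (source_id, gene, strand), ivals in sorted(groups.items()):
        ivals.sort()
        cur_start, cur_end = ivals[0]
        n = 1
        for start, end in ivals[1:]:
            if start < cur_end + merge_gap:
                cur_end = max(cur_end, end)
                n += 1
            else:
                fragments.append(
                    PredictedFragment(source_id, cur_start, cur_end, strand, gene, n)
                )
                cur_start, cur_end, n = start, end, 1
        fragments.append(
            PredictedFragment(source_id, cur_start, cur_end, strand, gene, n)
        )
    fragments.sort(key=lambda f: (f.source_id, f.start, f.end, f.gene, f.strand))
    return fragments


@dataclass
class CategoryCounts:
    """Counts of the five comparison categories for one gene class."""

    predictions: int = 0
    equal: int = 0
    delta_strand: int = 0
    different: int = 0
    fp: int = 0
    fn: int = 0
    n_reference: int = 0

    CATEGORIES = ("equal", "delta_strand", "fn", "fp", "different")

    def counts(self) -> Dict[str, int]:
        return {c: getattr(self, c) for c in self.CATEGORIES}

    def share_of_all(self) -> Dict[str, float]:
        """Each category over the sum of all five categories."""
        total = sum(self.counts().values())
        return {c: (v / total if total else 0.0) for c, v in self.counts().items()}

    def share_of_fragments(self) -> Dict[str, float]:
        """Each category over the number of predicted fragments."""
        return {
            c: (v / self.predictions if self.predictions else 0.0)
            for c, v in self.counts().items()
        }

    def per_reference(self) -> Dict[str, float]:
        """Each category normalized by the number of reference annotations."""
        return {
            c: (v / self.n_reference if self.n_reference else 0.0)
            for c, v in self.counts().items()
        }


@dataclass
class ComparisonReport:
    total: CategoryCounts
    per_class: Dict[str, CategoryCounts] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        def block(cc: CategoryCounts) -> Dict:
            return {
                "predictions": cc.predictions,
                "n_reference": cc.n_reference,
                "counts": cc.counts(),
                "share_of_all": cc.share_of_all(),
                "share_of_fragments": cc.share_of_fragments(),
                "per_reference": cc.per_reference(),
            }

        return {
            "total": block(self.total),
            "per_class": {cls: block(cc) for cls, cc in sorted(self.per_class.items())},
        }


def compare_annotations(
    fragments: Sequence[PredictedFragment],
    reference: Sequence[GeneAnnotation],
    min_share: float = 0.25,
    classes: Sequence[Tuple[str, str]] = DEFAULT_GENE_CLASSES,
) -> ComparisonReport:
    """Pair every fragment with its best-overlapping reference annotation and
    aggregate the five comparison categories.

    A reference annotation may partner several fragments.  Fragment
    categories (equal / Δ± / different / FP) are tallied under the gene
    class of the fragment's own gene; false negatives under the class of the
    missed reference gene.
    """
    by_source: Dict[str, List[Tuple[int, GeneAnnotation]]] = {}
    for i, ann in enumerate(reference):
        by_source.setdefault(ann.source_id, []).append((i, ann))

    total = CategoryCounts(predictions=len(fragments), n_reference=len(reference))
    per_class: Dict[str, CategoryCounts] = {}

    def cls_counts(gene: str) -> CategoryCounts:
        cls = gene_class(gene, classes)
        return per_class.setdefault(cls, CategoryCounts())

    matched: set = set()
    for frag in fragments:
        cc = cls_counts(frag.gene)
        cc.predictions += 1
        # partner: most shared positions; ties resolved deterministically
        cands = []
        for i, ann in by_source.get(frag.source_id, []):
            shared = min(frag.end, ann.end) - max(frag.start, ann.start)
            if shared > 0:
                cands.append((-shared, ann.gene, ann.strand, ann.start, ann.end, i))
        if not cands:
            total.fp += 1
            cc.fp += 1
            continue
        neg_shared, *_, idx = min(cands)
        if -neg_shared < min_share * frag.length:
            total.fp += 1
            cc.fp += 1
            continue
        matched.add(idx)
        ann = reference[idx]
        if ann.gene == frag.gene and ann.strand == frag.strand:
            total.equal += 1
            cc.equal += 1
        elif ann.gene == frag.gene:
            total.delta_strand += 1
            cc.delta_strand += 1
        else:
            total.different += 1
            cc.different += 1
    for i, ann in enumerate(reference):
        if i not in matched:
            total.fn += 1
            cls_counts(ann.gene).fn += 1
    for ann in reference:
        cls_counts(ann.gene).n_reference += 1
    return ComparisonReport(total=total, per_class=per_class)


@dataclass
class CoverageProfile:
    """Per gene key: summed marker overlap with the gene's annotated regions
    divided by their summed length.  A coverage of x means each nucleotide of
    the gene overlaps on average with x marker occurrences.  Keys with zero
    annotated length are reported as missing (``None``)."""

    coverage: Dict[GeneKey, Optional[float]]
    overlap: Dict[GeneKey, int]
    annotated_length: Dict[GeneKey, int]
    bins: Optional[Dict[GeneKey, np.ndarray]] = None


def gene_coverage(
    markers: Sequence[Marker],
    tree: TruncatedGST,
    annotations: Sequence[GeneAnnotation],
    n_bins: Optional[int] = None,
) -> CoverageProfile:
    """Marker coverage per gene key, optionally with a relative-position
    density histogram (overlap mass distributed over ``n_bins`` equal bins of
    relative gene position; the bins of a key sum to its total overlap)."""
    occs = classified_occurrences(markers, tree)
    by_key_src: Dict[GeneKey, Dict[str, List[Tuple[int, int]]]] = {}
    for occ in occs:
        key = GeneKey(occ.gene, occ.strand)
        by_key_src.setdefault(key, {}).setdefault(occ.source_id, []).append(
            (occ.start, occ.end)
        )
    ann_by_key: Dict[GeneKey, List[GeneAnnotation]] = {}
    for ann in annotations:
        ann_by_key.setdefault(ann.key, []).append(ann)

    keys = sorted(set(by_key_src) | set(ann_by_key))
    coverage: Dict[GeneKey, Optional[float]] = {}
    overlap_total: Dict[GeneKey, int] = {}
    lengths: Dict[GeneKey, int] = {}
    bins: Optional[Dict[GeneKey, np.ndarray]] = (
        {} if n_bins else None
    )
    for key in keys:
        anns = ann_by_key.get(key, [])
        length = sum(a.length for a in anns)
        lengths[key] = length
        total = 0
        hist = np.zeros(n_bins) if n_bins else None
        for ann in anns:
            for start, end in by_key_src.get(key, {}).get(ann.source_id, []):
                lo = max(start, ann.start)
                hi = min(end, ann.end)
                if hi <= lo:
                    continue
                total += hi - lo
                if hist is not None:
                    rel_lo = (lo - ann.start) / ann.length * n_bins
                    rel_hi = (hi - ann.start) / ann.length * n_bins
                    first, last = int(rel_lo), min(int(np.ceil(rel_hi)), n_bins)
                    for b in range(first, last):
                        frac = min(rel_hi, b + 1) - max(rel_lo, b)
                        hist[b] += frac / (rel_hi - rel_lo) * (hi - lo)
        overlap_total[key] = total
        coverage[key] = (total / length) if length else None
        if bins is not None:
            bins[key] = hist
    return CoverageProfile(coverage, overlap_total, lengths, bins)
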