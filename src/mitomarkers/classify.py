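"""Assign a target gene to each marker from the overlaps of its occurrences.

Every marker is located in all indexed sequences; each occurrence is mapped
back to forward genome coordinates (occurrences on the reverse-complement
copy are mirrored and flip the strand of any gene they touch), the shared
nucleotides with every annotated gene interval are summed per (gene,
strand), and the key with the highest total becomes the marker's target.
Argmax ties are broken lexicographically and flagged.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

from .gst import TruncatedGST
from .model import (FORWARD, ClassifiedOccurrence, GeneAnnotation, GeneKey,
                    Marker, flip_strand)


def _forward_occurrences(
    tree: TruncatedGST, word: str
) -> List[Tuple[str, int, int, bool]]:
    """Occurrences of ``word`` as (source_id, start, end, on_rc_copy) in
    forward genome coordinates."""
    out = []
    for occ in tree.find_all([word])[word]:
        seq = tree.sequences[occ.seq_index]
        if seq.strand == FORWARD:
            out.append((seq.source_id, occ.start, occ.end, False))
        else:
            L = seq.length
            out.append((seq.source_id, L - occ.end, L - occ.start, True))
    return out


def classify_markers(
    markers: Sequence[Marker],
    tree: TruncatedGST,
    annotations: Sequence[GeneAnnotation],
) -> Set[Marker]:
    """Return the markers with targets set to their argmax-overlap gene key.

    Markers whose occurrences touch no annotation become unassigned
    (``target=None``).  The result is deterministic under reordering of both
    markers and annotations.
    """
    if not annotations:
        raise ValueError("classification requires annotations")
    by_source: Dict[str, List[GeneAnnotation]] = {}
    for ann in annotations:
        by_source.setdefault(ann.source_id, []).append(ann)
    classified: Set[Marker] = set()
    for marker in markers:
        scores: Dict[GeneKey, int] = {}
        for source_id, start, end, on_rc in _forward_occurrences(tree, marker.word):
            for ann in by_source.get(source_id, []):
                ov = min(end, ann.end) - max(start, ann.start)
                if ov > 0:
                    strand = flip_strand(ann.strand) if on_rc else ann.strand
                    key = GeneKey(ann.gene, strand)
                    scores[key] = scores.get(key, 0) + ov
        if not scores:
            classified.add(marker.with_target(None, classified=True))
            continue
        best = max(scores.values())
        winners = sorted(k for k, v in scores.items() if v == best)
        classified.add(
            marker.with_target(
                winners[0],
                classified=True,
                tie=len(winners) > 1,
                target_overlap=best,
            )
        )
    return classified


def classified_occurrences(
    markers: Sequence[Marker], tree: TruncatedGST
) -> List[ClassifiedOccurrence]:
    """Occurrences of all targeted markers in forward genome coordinates.

    The effective strand of an occurrence is the target strand, flipped for
    occurrences found on the reverse-complement copy.  Unassigned markers
    are skipped.
    """
    out: List[ClassifiedOccurrence] = []
    for marker in sorted(markers, key=lambda m: (m.word, m.method)):
        if marker.target is None:
            continue
        for source_id, start, end, on_rc in _forward_occurrences(tree, marker.word):
            strand = flip_strand(marker.target.strand) if on_rc else marker.target.strand
            out.append(
                ClassifiedOccurrence(source_id, start, end, strand, marker.target.gene)
            )
    return out
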