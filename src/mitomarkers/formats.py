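"""Reading and writing the pipeline's file formats.

FASTA and BED6 come in; marker tables (TSV), fragment BED6 and comparison
reports (TSV/JSON) go out.  BED intervals are 0-based half-open, exactly the
internal convention, so coordinates pass through unchanged.  Genomes are
treated as linear strings; an optional wrap-around extension by k-1 symbols
is available for circular chromosomes but off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

from .evaluate import ComparisonReport, CoverageProfile, PredictedFragment
from .model import (FORWARD, REVERSE, GeneAnnotation, GeneKey, IndexedSequence,
                    Marker)

Genome = Tuple[str, str]


@dataclass
class Dataset:
    """Genomes with annotations and the derived index entries (one forward
    and one reverse-complement :class:`IndexedSequence` per genome)."""

    genomes: List[Genome]
    annotations: List[GeneAnnotation]
    derived: List[IndexedSequence]


def read_fasta(path) -> List[Genome]:
    """Ordered (id, residues) records; residues uppercased, U mapped to T."""
    genomes: List[Genome] = []
    seen: Set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate sequence identifier {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {record.id!r} has no sequence")
        genomes.append((record.id, seq))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes: Iterable[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path) -> List[GeneAnnotation]:
    """BED6 with the gene name in column 4 and strand in column 6."""
    annotations: List[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in (FORWARD, REVERSE):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} >= end {end_i}")
            annotations.append(GeneAnnotation(chrom, name, strand, start_i, end_i))
    return annotations


def write_bed(annotations: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for ann in sorted(annotations, key=lambda a: (a.source_id, a.start, a.end, a.gene)):
            fh.write(f"{ann.source_id}\t{ann.start}\t{ann.end}\t{ann.gene}\t0\t{ann.strand}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def expand_with_reverse_complements(
    genomes: Sequence[Genome], wrap: int = 0
) -> List[IndexedSequence]:
    """One forward and one reverse-complement index entry per genome.

    ``wrap`` > 0 appends the first ``wrap`` symbols to the end of each copy
    (circular chromosomes); default is plain linear treatment."""
    derived: List[IndexedSequence] = []
    for i, (source_id, seq) in enumerate(genomes):
        fwd = seq + seq[:wrap] if wrap else seq
        rc = reverse_complement(seq)
        rc = rc + rc[:wrap] if wrap else rc
        derived.append(IndexedSequence(2 * i, source_id, FORWARD, fwd))
        derived.append(IndexedSequence(2 * i + 1, source_id, REVERSE, rc))
    return derived


def make_dataset(
    genomes: Sequence[Genome], annotations: Sequence[GeneAnnotation], wrap: int = 0
) -> Dataset:
    known = {g[0] for g in genomes}
    missing = {a.source_id for a in annotations} - known
    if missing:
        raise ValueError(f"annotations reference unknown genomes: {sorted(missing)}")
    return Dataset(list(genomes), list(annotations),
                   expand_with_reverse_complements(genomes, wrap))


# -- marker tables ---------------------------------------------------------

MARKER_COLUMNS = (
    "word", "method", "gene", "strand", "support",
    "dominance", "u2", "p_word", "e1", "tie",
)


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_markers_tsv(markers: Iterable[Marker], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_COLUMNS) + "\n")
        for m in sorted(markers, key=lambda m: (m.word, m.method)):
            row = [
                m.word,
                m.method,
                m.target.gene if m.target else ".",
                m.target.strand if m.target else ".",
                str(m.support),
                _fmt(m.detail.get("dominance")),
                _fmt(m.detail.get("u2")),
                _fmt(m.detail.get("p_word")),
                _fmt(m.detail.get("e1")),
                _fmt(m.detail.get("tie")),
            ]
            fh.write("\t".join(row) + "\n")


def read_markers_tsv(path) -> Set[Marker]:
    markers: Set[Marker] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            target = (
                GeneKey(row["gene"], row["strand"]) if row["gene"] != "." else None
            )
            detail = {}
            for col in ("dominance", "u2", "p_word", "e1"):
                if row.get(col, ".") != ".":
                    detail[col] = float(row[col])
            if row.get("tie", ".") != ".":
                detail["tie"] = row["tie"] == "1"
            markers.add(
                Marker(row["word"], row["method"], target, int(row["support"]), detail)
            )
    return markers


# -- fragments and reports -------------------------------------------------

def write_fragments_bed(fragments: Iterable[PredictedFragment], path) -> None:
    with open(path, "w") as fh:
        for f in sorted(fragments, key=lambda f: (f.source_id, f.start, f.end, f.gene)):
            fh.write(
                f"{f.source_id}\t{f.start}\t{f.end}\t{f.gene}\t{f.n_occurrences}\t{f.strand}\n"
            )


def fragments_from_bed(path) -> List[PredictedFragment]:
    fragments = []
    for ann in read_bed(path):
        fragments.append(
            PredictedFragment(ann.source_id, ann.start, ann.end, ann.strand, ann.gene)
        )
    return fragments


def write_report_json(report: ComparisonReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report_tsv(report: ComparisonReport, path) -> None:
    """One row per gene class (plus total): prediction count, then for each
    category its share over all categories and its count per reference
    annotation — the layout of the published comparison tables, with both
    normalizations spelled out."""
    cats = ("equal", "delta_strand", "fn", "fp", "different")
    with open(path, "w") as fh:
        header = ["class", "predictions", "n_reference"]
        for c in cats:
            header += [f"{c}_count", f"{c}_share_all", f"{c}_per_reference"]
        fh.write("\t".join(header) + "\n")
        blocks = [("total", report.total)] + sorted(report.per_class.items())
        for name, cc in blocks:
            row = [name, str(cc.predictions), str(cc.n_reference)]
            share = cc.share_of_all()
            per_ref = cc.per_reference()
            for c in cats:
                row += [str(cc.counts()[c]), f"{share[c]:.4f}", f"{per_ref[c]:.4f}"]
            fh.write("\t".join(row) + "\n")


def write_coverage_tsv(profile: CoverageProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tstrand\tcoverage\toverlap\tannotated_length\n")
        for key in sorted(profile.coverage):
            cov = profile.coverage[key]
            fh.write(
                f"{key.gene}\t{key.strand}\t{'.' if cov is None else f'{cov:.6f}'}\t"
                f"{profile.overlap[key]}\t{profile.annotated_length[key]}\n"
            )
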