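"""Synthetic mitogenome-like datasets with known ground truth.

Each gene family has one random ancestral sequence; every genome carries a
point-mutated copy of each gene, genes are optionally reordered per genome
(mitogenomes rearrange during evolution), short random spacers separate
them, and base composition is AT-rich by default as in metazoan
mitochondria.  Alongside the clean truth annotations an "observed" set is
produced with injected errors — strand flips, gene renames, dropped and
spurious annotations — emulating a curated-database annotation layer of
imperfect quality.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formats import Dataset, make_dataset, write_bed, write_fasta
from .model import FORWARD, REVERSE, GeneAnnotation, flip_strand

#: Metazoan mitochondrial gene complement (approximate vertebrate lengths):
#: 13 protein-coding genes, 2 rRNAs, 22 tRNAs and the control region.
MITO_GENE_LENGTHS: Dict[str, int] = {
    "nad1": 956, "nad2": 1042, "nad3": 346, "nad4": 1378, "nad4l": 297,
    "nad5": 1812, "nad6": 525, "cox1": 1545, "cox2": 684, "cox3": 784,
    "atp6": 681, "atp8": 168, "cob": 1141,
    "rrnS": 950, "rrnL": 1559,
    "trnA": 69, "trnC": 66, "trnD": 68, "trnE": 69, "trnF": 71, "trnG": 68,
    "trnH": 69, "trnI": 71, "trnK": 70, "trnL1": 71, "trnL2": 71, "trnM": 69,
    "trnN": 73, "trnP": 70, "trnQ": 72, "trnR": 69, "trnS1": 68, "trnS2": 72,
    "trnT": 69, "trnV": 69, "trnW": 68, "trnY": 66,
    "OH": 980,
}

#: genes carried by the light strand in the typical vertebrate arrangement
MITO_MINUS_GENES = ("nad6", "trnQ", "trnA", "trnN", "trnC", "trnY", "trnE", "trnP")

MITO_GENE_STRANDS: Dict[str, str] = {
    g: (REVERSE if g in MITO_MINUS_GENES else FORWARD) for g in MITO_GENE_LENGTHS
}

#: A reduced gene complement (~3 kb genomes) for quick experiments that keep
#: the structure — proteins, rRNAs, tRNAs, control region, both strands.
MINI_GENE_LENGTHS: Dict[str, int] = {
    "nad1": 400, "cox1": 600, "cox2": 350, "cob": 450,
    "rrnS": 300, "rrnL": 450,
    "trnF": 70, "trnK": 70, "trnM": 70,
    "OH": 200,
}

MINI_GENE_STRANDS: Dict[str, str] = {
    g: (REVERSE if g in ("cox2", "trnK") else FORWARD) for g in MINI_GENE_LENGTHS
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AnnotationErrorRates:
    """Per-annotation probabilities of injected errors."""

    strand_flip: float = 0.0
    gene_rename: float = 0.0
    drop_annotation: float = 0.0
    spurious_annotation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("strand_flip", "gene_rename", "drop_annotation",
                     "spurious_annotation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass(frozen=True)
class SynthesisParams:
    n_genomes: int = 100
    gene_lengths: Mapping[str, int] = field(default_factory=lambda: dict(MITO_GENE_LENGTHS))
    gene_strands: Optional[Mapping[str, str]] = None
    mutation_rate: float = 0.05
    intergenic_min: int = 2
    intergenic_max: int = 20
    at_content: float = 0.70
    shuffle_gene_order: bool = True
    error_rates: AnnotationErrorRates = field(default_factory=AnnotationErrorRates)
    seed: int = 0

    def strands(self) -> Dict[str, str]:
        if self.gene_strands is not None:
            return dict(self.gene_strands)
        return {g: MITO_GENE_STRANDS.get(g, FORWARD) for g in self.gene_lengths}


def mini_params(**overrides) -> SynthesisParams:
    """Convenience preset with the reduced gene set."""
    base = SynthesisParams(
        gene_lengths=dict(MINI_GENE_LENGTHS), gene_strands=dict(MINI_GENE_STRANDS)
    )
    return replace(base, **overrides)


@dataclass
class SyntheticDataset:
    genomes: List[Tuple[str, str]]
    truth: List[GeneAnnotation]
    observed: List[GeneAnnotation]
    errors: List[Dict[str, str]]
    params: SynthesisParams

    def dataset(self, annotations: str = "observed") -> Dataset:
        ann = self.observed if annotations == "observed" else self.truth
        return make_dataset(self.genomes, ann)


def _random_seq(rng: np.random.Generator, length: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if hits.size:
        # substitute with one of the three other bases, uniformly
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def generate(params: SynthesisParams) -> SyntheticDataset:
    """Generate genomes, truth annotations, and error-injected observed
    annotations, deterministically from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    genes = sorted(params.gene_lengths)
    strands = params.strands()
    ancestors = {
        g: _random_seq(rng, params.gene_lengths[g], params.at_content) for g in genes
    }
    genomes: List[Tuple[str, str]] = []
    truth: List[GeneAnnotation] = []
    for gi in range(params.n_genomes):
        source_id = f"genome{gi:04d}"
        order = list(genes)
        if params.shuffle_gene_order:
            order = [genes[j] for j in rng.permutation(len(genes))]
        parts: List[np.ndarray] = []
        pos = 0
        for g in order:
            gap = int(rng.integers(params.intergenic_min, params.intergenic_max + 1))
            if gap:
                parts.append(_random_seq(rng, gap, params.at_content))
                pos += gap
            copy = _mutate(rng, ancestors[g], params.mutation_rate)
            strand = strands[g]
            placed = copy if strand == FORWARD else _revcomp_codes(copy)
            parts.append(placed)
            truth.append(GeneAnnotation(source_id, g, strand, pos, pos + len(placed)))
            pos += len(placed)
        genomes.append((source_id, _decode(np.concatenate(parts))))

    observed: List[GeneAnnotation] = []
    errors: List[Dict[str, str]] = []
    rates = params.error_rates
    gene_names = list(genes)
    for ann in truth:
        if rng.random() < rates.drop_annotation:
            errors.append({"source_id": ann.source_id, "kind": "drop",
                           "gene": ann.gene, "detail": f"{ann.start}-{ann.end}"})
            continue
        current = ann
        if rng.random() < rates.strand_flip:
            current = GeneAnnotation(ann.source_id, ann.gene,
                                     flip_strand(ann.strand), ann.start, ann.end)
            errors.append({"source_id": ann.source_id, "kind": "strand_flip",
                           "gene": ann.gene, "detail": f"{ann.start}-{ann.end}"})
        if len(gene_names) > 1 and rng.random() < rates.gene_rename:
            others = [g for g in gene_names if g != current.gene]
            new_gene = others[int(rng.integers(len(others)))]
            errors.append({"source_id": ann.source_id, "kind": "gene_rename",
                           "gene": ann.gene, "detail": f"renamed to {new_gene}"})
            current = GeneAnnotation(current.source_id, new_gene, current.strand,
                                     current.start, current.end)
        observed.append(current)
    if rates.spurious_annotation > 0:
        for source_id, seq in genomes:
            n_spur = rng.binomial(len(gene_names), rates.spurious_annotation)
            for _ in range(n_spur):
                g = gene_names[int(rng.integers(len(gene_names)))]
                length = min(params.gene_lengths[g], len(seq) - 1)
                start = int(rng.integers(0, len(seq) - length))
                strand = FORWARD if rng.random() < 0.5 else REVERSE
                observed.append(GeneAnnotation(source_id, g, strand, start, start + length))
                errors.append({"source_id": source_id, "kind": "spurious",
                               "gene": g, "detail": f"{start}-{start + length}"})
    return SyntheticDataset(genomes, truth, observed, errors, params)


def write_synthetic(ds: SyntheticDataset, outdir) -> None:
    """genomes.fasta, truth.bed, observed.bed and errors.tsv under outdir."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genomes, out / "genomes.fasta")
    write_bed(ds.truth, out / "truth.bed")
    write_bed(ds.observed, out / "observed.bed")
    with open(out / "errors.tsv", "w") as fh:
        fh.write("source_id\tkind\tgene\tdetail\n")
        for e in ds.errors:
            fh.write(f"{e['source_id']}\t{e['kind']}\t{e['gene']}\t{e['detail']}\n")
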