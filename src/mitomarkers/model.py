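"""Shared domain types.

Coordinates are 0-based, half-open ``[start, end)`` everywhere, matching BED.
A gene on the forward strand and the same gene on the reverse strand are kept
apart throughout: they are distinct :class:`GeneKey` values (``g+`` vs ``g-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

FORWARD = "+"
REVERSE = "-"

DNA_ALPHABET = "ACGT"

#: IUPAC one-letter codes tolerated in input sequences.  Index windows that
#: contain any symbol outside ``ACGT`` are simply not indexed.
IUPAC_EXTRA = "NRYSWKMBDHVU"


def flip_strand(strand: str) -> str:
    if strand == FORWARD:
        return REVERSE
    if strand == REVERSE:
        return FORWARD
    raise ValueError(f"unknown strand {strand!r}")


@dataclass(frozen=True)
class IndexedSequence:
    """One entry of the index: a genome copy on one orientation.

    ``strand`` is ``+`` for the original sequence and ``-`` for its
    reverse-complement copy; both copies of a genome share ``source_id``.
    ``residues`` may contain IUPAC ambiguity codes; windows touching them are
    skipped during indexing.
    """

    seq_index: int
    source_id: str
    strand: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Occurrence:
    """One placement of a substring: sequence ordinal plus ``[start, end)``."""

    seq_index: int
    start: int
    end: int


@dataclass(frozen=True, order=True)
class GeneKey:
    """A gene name together with the strand it is annotated on."""

    gene: str
    strand: str

    def flipped(self) -> "GeneKey":
        return GeneKey(self.gene, flip_strand(self.strand))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gene}{self.strand}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval on a source genome (forward coordinates, BED-like)."""

    source_id: str
    gene: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid annotation interval [{self.start}, {self.end}) "
                f"for {self.gene} on {self.source_id}"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene}")

    @property
    def key(self) -> GeneKey:
        return GeneKey(self.gene, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Marker:
    """A detected gene-indicator substring.

    ``detail`` carries method-specific diagnostics (dominance ratio for the
    annotation-guided method; the chi-square statistic ``u2``, word
    probability ``p_word`` and expected count ``e1`` for the probability-based
    method) and never takes part in equality or hashing.
    """

    word: str
    method: str  # "guided" | "probabilistic"
    target: Optional[GeneKey]
    support: int
    detail: Mapping[str, Any] = field(default_factory=dict, compare=False, hash=False)

    def with_target(self, target: Optional[GeneKey], **extra: Any) -> "Marker":
        detail = dict(self.detail)
        detail.update(extra)
        return Marker(self.word, self.method, target, self.support, detail)


@dataclass(frozen=True)
class ClassifiedOccurrence:
    """A marker occurrence mapped back to forward genome coordinates.

    ``strand`` is the effective strand of the indicated gene at this site: a
    marker targeting ``g+`` seen on the reverse-complement copy indicates
    ``g`` on the minus strand of the source genome.
    """

    source_id: str
    start: int
    end: int
    strand: str
    gene: str


@dataclass(frozen=True)
class PredictedFragment:
    """A merged run of overlapping marker occurrences with one target gene."""

    source_id: str
    start: int
    end: int
    strand: str
    gene: str
    n_occurrences: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start
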