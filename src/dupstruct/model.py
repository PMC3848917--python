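"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive (GFF3 convention). Gene order along a
chromosome is positional (``order_index``), assigned after excluding
transposable-element genes; strand is carried but never used by any
computation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class Mode(str, enum.Enum):
    """Duplication mode of a duplicate gene pair."""

    WGD_ALPHA = "wgd_alpha"
    WGD_BETA = "wgd_beta"
    WGD_GAMMA = "wgd_gamma"
    TANDEM = "tandem"
    PROXIMAL = "proximal"
    TRANSPOSED_RECENT = "transposed_recent"
    TRANSPOSED_OLD = "transposed_old"
    UNCLASSIFIED = "unclassified"


WGD_MODES = frozenset({Mode.WGD_ALPHA, Mode.WGD_BETA, Mode.WGD_GAMMA})
TRANSPOSED_MODES = frozenset({Mode.TRANSPOSED_RECENT, Mode.TRANSPOSED_OLD})


@dataclass
class GeneModel:
    """One gene locus, represented by its longest (max summed CDS) transcript."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    n_cds_exons: int
    cds_seq: str
    protein_seq: str
    is_te: bool = False
    order_index: Optional[int] = None

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def avg_exon_length(self) -> float:
        """Average coding-exon length in nucleotides."""
        return self.cds_length / self.n_cds_exons

    def validate(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.n_cds_exons < 1:
            raise ValueError(f"{self.gene_id}: n_cds_exons < 1")
        n_aa = len(self.protein_seq.rstrip("*"))
        if self.cds_length not in (3 * n_aa, 3 * (n_aa + 1)):
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} inconsistent with "
                f"protein length {n_aa} (expect 3*aa or 3*(aa+1) with terminal stop)"
            )


@dataclass(frozen=True)
class HomologyHit:
    """Directed similarity hit between two genes (BLAST-style)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) unordered pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass
class DuplicatePair:
    """An unordered duplicate gene pair with assigned mode and roles.

    ``parental_id``/``transposed_id`` are set iff the mode is transposed.
    """

    gene_a: str
    gene_b: str
    mode: Mode = Mode.UNCLASSIFIED
    parental_id: Optional[str] = None
    transposed_id: Optional[str] = None
    source_evalue: float = float("nan")

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
        if self.gene_a == self.gene_b:
            raise ValueError(f"degenerate pair ({self.gene_a}, {self.gene_b})")
        if (self.parental_id is None) != (self.transposed_id is None):
            raise ValueError("parental_id and transposed_id must be set together")
        if self.parental_id is not None:
            if {self.parental_id, self.transposed_id} != {self.gene_a, self.gene_b}:
                raise ValueError("roles must name the pair members")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class ExpressionProfile:
    gene_id: str
    values: Sequence[float]


@dataclass
class ColinearBlock:
    """A chain of colinearity anchors between the focal genome and one outgroup."""

    genome_pair: tuple[str, str]
    anchors: list[tuple[str, str]]  # (focal_gene_id, other_gene_id)
    score: float


@dataclass
class PairAlignment:
    """Global pairwise protein alignment; rows are gapped sequences."""

    row_a: str
    row_b: str
    source: str = "builtin"  # or "imported"

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        for i, (x, y) in enumerate(zip(self.row_a, self.row_b)):
            if x == "-" and y == "-":
                raise ValueError(f"column {i} gapped in both rows")

    @property
    def ungapped_a(self) -> str:
        return self.row_a.replace("-", "")

    @property
    def ungapped_b(self) -> str:
        return self.row_b.replace("-", "")


@dataclass(frozen=True)
class GapRun:
    """A maximal run of '-' in one alignment row (one indel)."""

    row: str  # "a" or "b"
    start_col: int
    length: int
    terminal: bool


@dataclass
class StructDiv:
    """The four structural-divergence measures plus per-copy indel statistics."""

    d_cds_len: int
    d_avg_exon_len: float
    n_indels: int
    max_indel_len: int
    n_indels_a: int
    n_indels_b: int
    max_indel_a: int
    max_indel_b: int


@dataclass
class RateEstimate:
    """NG86 Ka/Ks estimate; undefined rates are None (never 0)."""

    ka: Optional[float]
    ks: Optional[float]
    omega: Optional[float]
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # wilcoxon_exact | wilcoxon_normal | pearson_t | welch_t
    n_x: int
    n_y: int
    direction: int  # sign of location/association difference
    degenerate: bool = False


@dataclass
class SimTruthPair:
    gene_a: str
    gene_b: str
    mode: Mode
    epoch_label: str
    parental_id: Optional[str]
    transposed_id: Optional[str]
    target_ks: float
    n_indel_events_a: int
    n_indel_events_b: int
    truncated_fraction: float
    in_family: bool

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.gene_a, self.gene_b)


@dataclass
class SimTruth:
    """Ground-truth event log of one simulated dataset."""

    pairs: list[SimTruthPair] = field(default_factory=list)
    # gene_id -> set of outgroup labels in which the gene is anchored
    gene_outgroups: dict[str, set[str]] = field(default_factory=dict)

    def pairs_of_mode(self, mode: Mode) -> list[SimTruthPair]:
        return [p for p in self.pairs if p.mode == mode]
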