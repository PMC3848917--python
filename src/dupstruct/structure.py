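"""Structural divergence between duplicated proteins.

Each duplicate pair is globally aligned (affine-gap Needleman-Wunsch,
BLOSUM62, gap open 10 / extend 0.5 by default); maximal runs of '-' in
either alignment row are indels. Four headline measures are computed per
pair — absolute difference in coding-region length (nt), absolute
difference in average coding-exon length (nt), indel count, and maximum
indel length (alignment columns, amino-acid units) — plus per-copy indel
counts and maxima for the parental/transposed asymmetry analysis.

Terminal gaps are counted as indels: coding-length differences necessarily
surface as terminal gaps and excluding them would silently drop that
signal. Pre-computed alignments (aligned FASTA, two records per file) can
be imported in place of the builtin aligner; metrics are aligner-agnostic.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .model import DuplicatePair, GapRun, GeneModel, PairAlignment, StructDiv

logger = logging.getLogger("dupstruct.structure")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class AlignParams:
    """Alignment scoring parameters (BLOSUM62, affine gaps).

    A gap of length L costs ``gap_open + (L-1) * gap_extend``. With
    ``end_gap_free`` terminal gaps are scored with the extension penalty
    only (off by default). Residues outside the standard 20-letter
    alphabet are treated as 'X' with substitution score 0.
    """

    def __init__(self, gap_open: float = 10.0, gap_extend: float = 0.5,
                 matrix: str = "BLOSUM62", end_gap_free: bool = False):
        self.gap_open = float(gap_open)
        self.gap_extend = float(gap_extend)
        self.matrix_name = matrix
        self.end_gap_free = end_gap_free
        m = substitution_matrices.load(matrix)
        m = m.copy()
        xi = m.alphabet.index("X")
        for j in range(len(m.alphabet)):
            m[xi, j] = 0.0
            m[j, xi] = 0.0
        self.matrix = m

    def make_aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = self.matrix
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        if self.end_gap_free:
            a.target_end_open_gap_score = -self.gap_extend
            a.target_end_extend_gap_score = -self.gap_extend
            a.query_end_open_gap_score = -self.gap_extend
            a.query_end_extend_gap_score = -self.gap_extend
        return a


def _sanitize(seq: str, which: str) -> str:
    if not seq:
        raise ValueError(f"empty protein sequence ({which})")
    if seq.endswith("*"):
        logger.warning("terminal stop '*' stripped from %s", which)
        seq = seq.rstrip("*")
    if not seq:
        raise ValueError(f"protein sequence {which} is only stop codons")
    if "*" in seq:
        raise ValueError(f"internal stop in protein sequence ({which})")
    cleaned = []
    for c in seq.upper():
        if c in _STANDARD_AA:
            cleaned.append(c)
        else:
            logger.warning("non-standard residue %r in %s treated as X", c, which)
            cleaned.append("X")
    return "".join(cleaned)


def align_pair(
    protein_a: str, protein_b: str, params: Optional[AlignParams] = None
) -> PairAlignment:
    """Optimal global alignment of two protein sequences.

    Deterministic: among co-optimal alignments the library's first
    traceback is taken, and the input pair is canonically ordered
    internally so that ``align_pair(a, b)`` and ``align_pair(b, a)``
    return row-swapped identical alignments.
    """
    params = params or AlignParams()
    a = _sanitize(protein_a, "a")
    b = _sanitize(protein_b, "b")
    swap = b < a
    x, y = (b, a) if swap else (a, b)
    aligner = params.make_aligner()
    aln = aligner.align(x, y)[0]
    row_x, row_y = str(aln[0]), str(aln[1])
    if swap:
        row_x, row_y = row_y, row_x
    return PairAlignment(row_a=row_x, row_b=row_y, source="builtin")


_GAP_RE = re.compile(r"-+")


def extract_gap_runs(aln: PairAlignment) -> list[GapRun]:
    """Every maximal run of '-' in either row, as one indel each.

    Terminal runs (touching either end of the alignment) are flagged."""
    runs: list[GapRun] = []
    n = len(aln.row_a)
    for row_label, row in (("a", aln.row_a), ("b", aln.row_b)):
        for m in _GAP_RE.finditer(row):
            runs.append(GapRun(
                row=row_label,
                start_col=m.start(),
                length=m.end() - m.start(),
                terminal=(m.start() == 0 or m.end() == n),
            ))
    runs.sort(key=lambda r: (r.start_col, r.row))
    return runs


def structural_metrics(
    pair: DuplicatePair,
    genes: Mapping[str, GeneModel],
    aln: PairAlignment,
) -> StructDiv:
    """The four structural-divergence measures plus per-copy indel stats.

    A gap run in row x is attributed to gene x (a gap in x's row is
    structural absence in x). Symmetric in pair order for the headline
    measures; per-copy fields swap consistently.
    """
    ga, gb = genes[pair.gene_a], genes[pair.gene_b]
    runs = extract_gap_runs(aln)
    runs_a = [r for r in runs if r.row == "a"]
    runs_b = [r for r in runs if r.row == "b"]
    return StructDiv(
        d_cds_len=abs(ga.cds_length - gb.cds_length),
        d_avg_exon_len=abs(ga.avg_exon_length - gb.avg_exon_length),
        n_indels=len(runs),
        max_indel_len=max((r.length for r in runs), default=0),
        n_indels_a=len(runs_a),
        n_indels_b=len(runs_b),
        max_indel_a=max((r.length for r in runs_a), default=0),
        max_indel_b=max((r.length for r in runs_b), default=0),
    )


# ---------------------------------------------------------------------------
# parental/transposed asymmetry
# ---------------------------------------------------------------------------

#: per-copy features compared between parental (P) and transposed (T) copies
ASYMMETRY_FEATURES = ("cds_length", "avg_exon_length", "n_indels", "max_indel")

_REAL_TOL = 1e-9


def asymmetry_percentages(
    records: Iterable[tuple[DuplicatePair, StructDiv]],
    genes: Mapping[str, GeneModel],
) -> dict[str, dict[str, float]]:
    """Percentages of greater/equal/less relationships of per-copy
    structural features between parental and transposed copies.

    For each feature the three percentages sum to 100. 'Equal' is exact for
    integer features and |delta| < 1e-9 for the real-valued exon measure.
    """
    counts: dict[str, dict[str, int]] = {
        f: {"parental_greater": 0, "equal": 0, "parental_less": 0}
        for f in ASYMMETRY_FEATURES
    }
    n = 0
    for pair, sd in records:
        if pair.parental_id is None:
            continue
        n += 1
        par_is_a = pair.parental_id == pair.gene_a
        gp, gt = genes[pair.parental_id], genes[pair.transposed_id]
        per_copy = {
            "cds_length": (gp.cds_length, gt.cds_length),
            "avg_exon_length": (gp.avg_exon_length, gt.avg_exon_length),
            "n_indels": (sd.n_indels_a, sd.n_indels_b) if par_is_a
                        else (sd.n_indels_b, sd.n_indels_a),
            "max_indel": (sd.max_indel_a, sd.max_indel_b) if par_is_a
                         else (sd.max_indel_b, sd.max_indel_a),
        }
        for feat, (p, t) in per_copy.items():
            tol = _REAL_TOL if feat == "avg_exon_length" else 0
            if abs(p - t) <= tol:
                counts[feat]["equal"] += 1
            elif p > t:
                counts[feat]["parental_greater"] += 1
            else:
                counts[feat]["parental_less"] += 1
    if n == 0:
        logger.warning("no transposed pairs with roles; empty asymmetry report")
        return {f: {k: float("nan") for k in c} for f, c in counts.items()}
    return {
        f: {k: 100.0 * v / n for k, v in c.items()} for f, c in counts.items()
    }


# ---------------------------------------------------------------------------
# alignment import
# ---------------------------------------------------------------------------

def load_alignment(directory: str | Path, gene_a: str, gene_b: str) -> Optional[PairAlignment]:
    """Load a pre-computed aligned-FASTA pair alignment if present.

    Files are named ``<geneA>__<geneB>.afa`` (canonical order) and hold two
    records whose ids name the genes; rows are matched to the pair by id,
    not record order.
    """
    directory = Path(directory)
    path = directory / f"{gene_a}__{gene_b}.afa"
    if not path.exists():
        path = directory / f"{gene_b}__{gene_a}.afa"
        if not path.exists():
            return None
    recs = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if set(recs) != {gene_a, gene_b}:
        raise ValueError(f"{path}: records do not name the pair ({sorted(recs)})")
    return PairAlignment(row_a=recs[gene_a], row_b=recs[gene_b], source="imported")
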