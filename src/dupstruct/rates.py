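"""Codon alignment and Nei-Gojobori (1986) Ka/Ks estimation.

The protein alignment of a duplicate pair is back-translated to a codon
alignment, then Ka and Ks are estimated by the NG86 counting method:
fractional synonymous/non-synonymous site counts per codon (the fraction of
the nine single-base neighbours that are synonymous, normalized so each
codon contributes exactly three sites; changes to stop codons count as
non-synonymous), observed differences resolved by equal-weight averaging
over all minimal mutation pathways (pathways through stop codons skipped),
and a Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p) applied to the
proportions. A proportion >= 3/4 saturates the correction and the
corresponding rate is undefined (None, never 0).

The estimator interface is pluggable: anything callable as
``estimator(codon_alignment) -> RateEstimate`` can replace
:func:`ng86_rates` downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

from Bio.Data import CodonTable

from .model import PairAlignment, RateEstimate

logger = logging.getLogger("dupstruct.rates")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_FORWARD = dict(_TABLE.forward_table)
_BASES = "ACGT"
GAP_CODON = "---"


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a codon, None for stops/ambiguous codons."""
    return _FORWARD.get(codon)


def is_clean(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon)


@dataclass
class CodonAlignment:
    """Two equal-length rows of codon-or-gap triplets."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows must have equal length")

    @property
    def n_compared_codons(self) -> int:
        """Columns with no gap and no ambiguous base in either row."""
        return sum(
            1
            for ca, cb in zip(self.codons_a, self.codons_b)
            if is_clean(ca) and is_clean(cb)
        )

    def compared_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if is_clean(ca) and is_clean(cb)
        ]

    def swapped(self) -> "CodonAlignment":
        return CodonAlignment(self.codons_b, self.codons_a)


def _strip_terminal_stop(cds: str, n_aa: int, which: str) -> str:
    cds = cds.upper()
    if len(cds) == 3 * (n_aa + 1) and cds[-3:] in _STOPS:
        return cds[:-3]
    if len(cds) == 3 * n_aa:
        return cds
    raise ValueError(
        f"CDS length {len(cds)} of {which} inconsistent with ungapped protein "
        f"length {n_aa} (expect 3*aa, or 3*(aa+1) with a terminal stop)"
    )


def back_translate(aln: PairAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Expand a protein alignment to a codon alignment using source CDSs.

    Each amino acid is replaced by its source codon, each gap column by a
    triplet gap; terminal stop codons are dropped. A codon that does not
    translate to its aligned residue is an error naming the position.
    """
    rows = []
    for row, cds, which in ((aln.row_a, cds_a, "a"), (aln.row_b, cds_b, "b")):
        n_aa = len(row) - row.count("-")
        cds = _strip_terminal_stop(cds, n_aa, which)
        codons = []
        k = 0
        for col, res in enumerate(row):
            if res == "-":
                codons.append(GAP_CODON)
                continue
            codon = cds[3 * k : 3 * k + 3]
            k += 1
            aa = translate_codon(codon)
            if aa is not None and res != "X" and aa != res:
                raise ValueError(
                    f"row {which}, alignment column {col}: codon {codon} "
                    f"translates to {aa}, aligned residue is {res}"
                )
            codons.append(codon)
        rows.append(codons)
    return CodonAlignment(rows[0], rows[1])


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _neighbours(codon: str) -> list[str]:
    out = []
    for i, base in enumerate(codon):
        for b in _BASES:
            if b != base:
                out.append(codon[:i] + b + codon[i + 1 :])
    return out


def _site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, non-synonymous) sites of one codon.

    Each codon contributes exactly 3 sites; a single-base change to a stop
    codon counts as non-synonymous.
    """
    aa = translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} in coding sequence")
    syn = sum(1 for nb in _neighbours(codon) if translate_codon(nb) == aa)
    return syn / 3.0, 3.0 - syn / 3.0


_SITE_CACHE: dict[str, tuple[float, float]] = {}


def codon_sites(codon: str) -> tuple[float, float]:
    if codon not in _SITE_CACHE:
        _SITE_CACHE[codon] = _site_counts(codon)
    return _SITE_CACHE[codon]


def _pathway_steps(c1: str, c2: str) -> list[list[tuple[str, str]]]:
    """All minimal mutation pathways from c1 to c2, as lists of steps."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    pathways = []
    for order in permutations(diff):
        cur = c1
        steps = []
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        pathways.append(steps)
    return pathways


def _diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Fractional (synonymous, non-synonymous) differences between codons.

    Minimal pathways are weighted equally; pathways whose intermediate
    codons are stops are skipped (if every pathway is blocked, all are
    used as a fallback).
    """
    if c1 == c2:
        return 0.0, 0.0
    pathways = _pathway_steps(c1, c2)
    open_paths = [
        p for p in pathways
        if all(translate_codon(b) is not None for _, b in p[:-1])
    ]
    if not open_paths:
        open_paths = pathways
    sd = nd = 0.0
    w = 1.0 / len(open_paths)
    for p in open_paths:
        for a, b in p:
            if translate_codon(a) is not None and translate_codon(a) == translate_codon(b):
                sd += w
            else:
                nd += w
    return sd, nd


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    if key not in _DIFF_CACHE:
        _DIFF_CACHE[key] = _diff_counts(c1, c2)
    return _DIFF_CACHE[key]


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None at/beyond saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_rates(caln: CodonAlignment) -> RateEstimate:
    """NG86 Ka/Ks for one codon alignment.

    Symmetric in row order; S + N = 3 * n_compared_codons. Internal stop
    codons in a compared column are an error (the pair is rejected
    upstream with a diagnostic).
    """
    cols = caln.compared_columns()
    if not cols:
        raise ValueError("no comparable codon columns")
    s1 = n1 = s2 = n2 = 0.0
    sd = nd = 0.0
    for ca, cb in cols:
        if translate_codon(ca) is None or translate_codon(cb) is None:
            raise ValueError(f"internal stop codon in compared column ({ca}/{cb})")
        a_s, a_n = codon_sites(ca)
        b_s, b_n = codon_sites(cb)
        s1 += a_s
        n1 += a_n
        s2 += b_s
        n2 += b_n
        d_s, d_n = codon_diffs(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s1 + s2) / 2.0
    n_sites = (n1 + n2) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None:
        logger.info("Ks saturated (pS=%.3f >= 3/4); undefined", ps)
    omega: Optional[float] = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return RateEstimate(
        ka=ka, ks=ks, omega=omega,
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        n_codons=len(cols),
    )


def pair_rates(aln: PairAlignment, cds_a: str, cds_b: str) -> RateEstimate:
    """Convenience: back-translate then estimate NG86 rates."""
    return ng86_rates(back_translate(aln, cds_a, cds_b))
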