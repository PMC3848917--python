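"""Protein alignment, gap-run extraction and structural-divergence measures."""

import random

import pytest

from dupstruct.model import DuplicatePair, GeneModel, PairAlignment
from dupstruct.structure import (
    AlignParams,
    align_pair,
    asymmetry_percentages,
    extract_gap_runs,
    load_alignment,
    structural_metrics,
)

from oracles import brute_force_align_score

AA = "ACDEFGHIKLMNPQRSTVWY"
PARAMS = AlignParams()


def _score(aln: PairAlignment, params: AlignParams = PARAMS) -> float:
    """Score an alignment under the affine convention (independent of the
    aligner's own reported score)."""
    total = 0.0
    for row in ("a", "b"):
        gaps = [r for r in extract_gap_runs(aln) if r.row == row]
        total -= sum(params.gap_open + (r.length - 1) * params.gap_extend for r in gaps)
    for x, y in zip(aln.row_a, aln.row_b):
        if x != "-" and y != "-":
            total += params.matrix[x, y]
    return total


# ---------------------------------------------------------------------------
# aligner
# ---------------------------------------------------------------------------

def test_identical_sequences_align_gapless_with_diagonal_score():
    aln = align_pair("MKT", "MKT")
    assert (aln.row_a, aln.row_b) == ("MKT", "MKT")
    expected = sum(PARAMS.matrix[c, c] for c in "MKT")
    assert _score(aln) == expected


def test_single_deletion_yields_one_single_column_gap():
    a = "MKTAYIAK"
    b = "MKTYIAK"  # A deleted
    aln = align_pair(a, b)
    runs = extract_gap_runs(aln)
    assert len(runs) == 1
    assert runs[0].row == "b" and runs[0].length == 1
    assert aln.ungapped_a == a and aln.ungapped_b == b


def test_alignment_symmetric_under_argument_swap():
    rnd = random.Random(0)
    for _ in range(20):
        a = "".join(rnd.choice(AA) for _ in range(rnd.randint(3, 12)))
        b = "".join(rnd.choice(AA) for _ in range(rnd.randint(3, 12)))
        ab = align_pair(a, b)
        ba = align_pair(b, a)
        assert (ab.row_a, ab.row_b) == (ba.row_b, ba.row_a)


def test_aligner_score_matches_exhaustive_search():
    """Builtin alignment score equals full enumeration of every global
    affine-gap alignment for short sequences."""
    rnd = random.Random(7)
    sub = lambda x, y: float(PARAMS.matrix[x, y])
    for _ in range(60):
        a = "".join(rnd.choice(AA) for _ in range(rnd.randint(1, 6)))
        b = "".join(rnd.choice(AA) for _ in range(rnd.randint(1, 6)))
        best = brute_force_align_score(a, b, sub, PARAMS.gap_open, PARAMS.gap_extend)
        aln = align_pair(a, b)
        assert _score(aln) == pytest.approx(best), (a, b)


def test_align_pair_input_validation():
    with pytest.raises(ValueError):
        align_pair("", "MKT")
    aln = align_pair("MKT*", "MKT")  # terminal stop stripped with warning
    assert aln.ungapped_a == "MKT"
    aln = align_pair("MKU", "MKT")  # non-standard residue -> X, score 0
    assert aln.row_a == "MKX"


# ---------------------------------------------------------------------------
# gap runs
# ---------------------------------------------------------------------------

def test_gap_runs_hand_enumerated_columns():
    aln = PairAlignment("MKT-AYL", "MK-CAYL")
    runs = extract_gap_runs(aln)
    assert {(r.row, r.start_col, r.length) for r in runs} == \
        {("b", 2, 1), ("a", 3, 1)}
    assert all(not r.terminal for r in runs)


def test_gap_runs_terminal_flag():
    aln = PairAlignment("ACDEFG----", "ACD---GHIK")
    runs = {(r.row, r.start_col): r for r in extract_gap_runs(aln)}
    assert runs[("b", 3)].length == 3 and not runs[("b", 3)].terminal
    assert runs[("a", 6)].length == 4 and runs[("a", 6)].terminal


def test_gapless_alignment_has_no_runs():
    assert extract_gap_runs(PairAlignment("MKT", "MRT")) == []


def test_column_gapped_in_both_rows_rejected():
    with pytest.raises(ValueError, match="both rows"):
        PairAlignment("M-T", "M-T")


# ---------------------------------------------------------------------------
# structural metrics
# ---------------------------------------------------------------------------

def _gene(gid, cds_len, n_exons, protein=None, cds=None):
    return GeneModel(gene_id=gid, chromosome="chr1", start=1, end=cds_len + 1,
                     strand="+", n_cds_exons=n_exons,
                     cds_seq=cds or "A" * cds_len,
                     protein_seq=protein or "X" * (cds_len // 3))


def test_structural_metrics_arithmetic_fixture():
    """300 nt/3 exons vs 240 nt/2 exons with one 20-column gap in row b:
    d_cds_len 60, d_avg_exon_len |100-120| = 20, one indel of length 20
    attributed to copy b."""
    genes = {"gA": _gene("gA", 300, 3), "gB": _gene("gB", 240, 2)}
    row_a = "M" * 100
    row_b = "M" * 40 + "-" * 20 + "M" * 40
    sd = structural_metrics(DuplicatePair("gA", "gB"), genes,
                            PairAlignment(row_a, row_b))
    assert sd.d_cds_len == 60
    assert sd.d_avg_exon_len == pytest.approx(20.0)
    assert (sd.n_indels, sd.max_indel_len) == (1, 20)
    assert (sd.n_indels_a, sd.n_indels_b) == (0, 1)
    assert (sd.max_indel_a, sd.max_indel_b) == (0, 20)


def test_identical_duplicates_have_zero_divergence():
    genes = {"gA": _gene("gA", 300, 3), "gB": _gene("gB", 300, 3)}
    sd = structural_metrics(DuplicatePair("gA", "gB"), genes,
                            PairAlignment("M" * 100, "M" * 100))
    assert (sd.d_cds_len, sd.d_avg_exon_len, sd.n_indels, sd.max_indel_len) == \
        (0, 0.0, 0, 0)


def test_equal_lengths_with_balanced_indels_are_not_redundant():
    """One insertion plus one equal-size deletion: d_cds_len 0 but
    n_indels 2 — the measures capture different signals."""
    genes = {"gA": _gene("gA", 300, 2), "gB": _gene("gB", 300, 2)}
    row_a = "M" * 30 + "-" * 5 + "M" * 70
    row_b = "M" * 60 + "-" * 5 + "M" * 40
    sd = structural_metrics(DuplicatePair("gA", "gB"), genes,
                            PairAlignment(row_a, row_b))
    assert sd.d_cds_len == 0 and sd.n_indels == 2


def test_metrics_symmetric_in_pair_order(small_metrics):
    sim, res, metrics = small_metrics
    row = metrics.iloc[0]
    ga, gb = row.gene_a, row.gene_b
    aln = align_pair(sim.genes[ga].protein_seq, sim.genes[gb].protein_seq)
    fwd = structural_metrics(DuplicatePair(ga, gb), sim.genes, aln)
    swapped = PairAlignment(aln.row_b, aln.row_a)
    rev = structural_metrics(DuplicatePair(ga, gb), sim.genes, swapped)
    assert (fwd.d_cds_len, fwd.d_avg_exon_len, fwd.n_indels, fwd.max_indel_len) == \
        (rev.d_cds_len, rev.d_avg_exon_len, rev.n_indels, rev.max_indel_len)
    assert (fwd.n_indels_a, fwd.n_indels_b) == (rev.n_indels_b, rev.n_indels_a)


def test_alignment_length_and_indel_count_invariants(small_metrics):
    """Alignment length = len(a) + gaps in row a = len(b) + gaps in row b;
    n_indels = n_indels_a + n_indels_b; max = max of per-copy maxima
    (checked across all simulated pairs)."""
    sim, res, metrics = small_metrics
    assert (metrics.n_indels == metrics.n_indels_a + metrics.n_indels_b).all()
    assert (metrics.max_indel_len ==
            metrics[["max_indel_a", "max_indel_b"]].max(axis=1)).all()
    for row in metrics.head(25).itertuples():
        a = sim.genes[row.gene_a].protein_seq
        b = sim.genes[row.gene_b].protein_seq
        aln = align_pair(a, b)
        gaps_a = aln.row_a.count("-")
        gaps_b = aln.row_b.count("-")
        assert len(aln.row_a) == len(a) + gaps_a == len(b) + gaps_b
        # protein-length difference equals the net gap imbalance
        assert gaps_a - gaps_b == len(b) - len(a)
        if len(a) != len(b):
            assert row.n_indels >= 1


# ---------------------------------------------------------------------------
# asymmetry
# ---------------------------------------------------------------------------

def test_asymmetry_identical_copies_all_equal():
    genes = {"gA": _gene("gA", 300, 3), "gB": _gene("gB", 300, 3)}
    pair = DuplicatePair("gA", "gB", parental_id="gA", transposed_id="gB")
    sd = structural_metrics(pair, genes, PairAlignment("M" * 100, "M" * 100))
    pct = asymmetry_percentages([(pair, sd)], genes)
    for feat in pct:
        assert pct[feat]["equal"] == pytest.approx(100.0)


def test_asymmetry_single_truncated_pair():
    genes = {"gA": _gene("gA", 300, 3), "gB": _gene("gB", 200, 2)}
    pair = DuplicatePair("gA", "gB", parental_id="gA", transposed_id="gB")
    aln = PairAlignment("M" * 100, "M" * 66 + "-" * 34)
    sd = structural_metrics(pair, genes, aln)
    pct = asymmetry_percentages([(pair, sd)], genes)
    assert pct["cds_length"]["parental_greater"] == pytest.approx(100.0)
    assert pct["n_indels"]["parental_less"] == pytest.approx(100.0)
    total = sum(pct["avg_exon_length"].values())
    assert total == pytest.approx(100.0, abs=0.01)


# ---------------------------------------------------------------------------
# alignment import
# ---------------------------------------------------------------------------

def test_imported_alignment_reproduces_builtin_metrics(tmp_path, small_metrics):
    """An imported aligned-FASTA identical to the builtin alignment yields
    identical metrics."""
    sim, res, metrics = small_metrics
    row = metrics.iloc[0]
    pair = DuplicatePair(row.gene_a, row.gene_b)
    aln = align_pair(sim.genes[row.gene_a].protein_seq,
                     sim.genes[row.gene_b].protein_seq)
    afa = tmp_path / f"{row.gene_a}__{row.gene_b}.afa"
    afa.write_text(f">{row.gene_a}\n{aln.row_a}\n>{row.gene_b}\n{aln.row_b}\n")
    loaded = load_alignment(tmp_path, row.gene_a, row.gene_b)
    assert loaded.source == "imported"
    sd_builtin = structural_metrics(pair, sim.genes, aln)
    sd_import = structural_metrics(pair, sim.genes, loaded)
    assert sd_builtin == sd_import
    assert load_alignment(tmp_path, "nope", "nada") is None
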