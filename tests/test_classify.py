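"""Duplication-mode classification: filtering, local rules, colinearity
chaining (vs exhaustive enumeration), ancestral loci, epochs, precedence."""

import random

import pytest

from dupstruct.classify import (
    Anchor,
    ClassifierConfig,
    ancestral_loci,
    assign_epochs,
    build_paralog_map,
    chain_colinear_anchors,
    classify_all,
    exclude_te_and_assign_order,
    filter_hits,
    find_proximal,
    find_tandem,
    find_transposed,
)
from dupstruct.model import ColinearBlock, GeneModel, HomologyHit, Mode

from conftest import classifier_config, small_config
from oracles import enumerate_chains


def _gene(gid, chrom="chr1", start=0, end=None, is_te=False):
    return GeneModel(gene_id=gid, chromosome=chrom, start=start,
                     end=end if end is not None else start + 10, strand="+",
                     n_cds_exons=1, cds_seq="", protein_seq="", is_te=is_te)


def _universe(n=10, chrom="chr1"):
    genes = {f"g{i}": _gene(f"g{i}", chrom, start=100 * i) for i in range(n)}
    return exclude_te_and_assign_order(genes)


# ---------------------------------------------------------------------------
# hit filtering
# ---------------------------------------------------------------------------

def test_filter_hits_strict_cutoff_and_top_n():
    """E-value exactly at the cutoff is removed (strict <); per query only
    the top-N subjects by ascending E-value survive."""
    hits = [HomologyHit("q", f"s{i}", 10.0 ** -(20 + i), 50.0) for i in range(7)]
    hits.append(HomologyHit("q", "s_at_cutoff", 1e-10, 99.0))
    hits.append(HomologyHit("q2", "sA", 1e-30, 10.0))
    kept = filter_hits(hits, max_evalue=1e-10, top_n=5)
    by_q = {}
    for h in kept:
        by_q.setdefault(h.query_id, []).append(h.subject_id)
    assert by_q["q"] == ["s6", "s5", "s4", "s3", "s2"]  # 5 smallest E-values
    assert by_q["q2"] == ["sA"]
    assert all(h.subject_id != "s_at_cutoff" for h in kept)

    three = filter_hits(hits[:3], max_evalue=1e-10, top_n=5)
    assert len(three) == 3  # under quota: all kept
    with pytest.raises(ValueError):
        filter_hits(hits, top_n=0)


def test_filter_hits_tie_break_bitscore_then_id():
    hits = [
        HomologyHit("q", "sB", 1e-20, 100.0),
        HomologyHit("q", "sA", 1e-20, 100.0),
        HomologyHit("q", "sC", 1e-20, 200.0),
    ]
    kept = filter_hits(hits, top_n=2)
    assert [h.subject_id for h in kept] == ["sC", "sA"]


# ---------------------------------------------------------------------------
# order assignment, tandem, proximal
# ---------------------------------------------------------------------------

def test_te_exclusion_and_order_indices():
    genes = {f"g{i}": _gene(f"g{i}", "chr1" if i < 6 else "chr2", 100 * i)
             for i in range(10)}
    universe = exclude_te_and_assign_order(genes, te_ids={"g2", "g7"})
    assert len(universe) == 8
    assert [universe[f"g{i}"].order_index for i in (0, 1, 3, 4, 5)] == [0, 1, 2, 3, 4]
    assert [universe[f"g{i}"].order_index for i in (6, 8, 9)] == [0, 1, 2]


def test_order_tie_broken_by_end_then_id():
    """Two genes with identical start: deterministic order by end then id,
    for either construction order."""
    for order in (("gA", "gB"), ("gB", "gA")):
        genes = {}
        for gid in order:
            genes[gid] = _gene(gid, start=500, end=600 if gid == "gA" else 550)
        universe = exclude_te_and_assign_order(genes)
        assert universe["gB"].order_index == 0  # smaller end wins
        assert universe["gA"].order_index == 1


def test_find_tandem_consecutive_only():
    universe = _universe(8)
    universe["h0"] = _gene("h0", "chr2", 0)
    universe = exclude_te_and_assign_order(universe)
    pairs = {("g5", "g6"): 1e-30, ("g2", "g4"): 1e-30, ("g5", "h0"): 1e-30}
    assert find_tandem(pairs, universe) == {("g5", "g6")}


def test_find_proximal_rules():
    """Non-paralogous intervening genes < 10; intervening paralogs of either
    member do not count (a fully-paralogous gap is still proximal)."""
    universe = _universe(20)
    base = {("g2", "g4"): 1e-30}  # one intervening gene (g3)
    pmap = build_paralog_map(base)
    assert find_proximal(base, universe, pmap) == {("g2", "g4")}

    far = {("g2", "g14"): 1e-30}  # 11 intervening genes
    assert find_proximal(far, universe, build_paralog_map(far)) == set()

    # g3, g4 both paralogs of g2 -> 0 non-paralogous intervening -> proximal
    pairs = {("g2", "g5"): 1e-30, ("g2", "g3"): 1e-40, ("g2", "g4"): 1e-40}
    pmap = build_paralog_map(pairs)
    assert ("g2", "g5") in find_proximal(pairs, universe, pmap)

    # max_intervening is an upper bound on the count, 9 ok / 10 not
    nine = {("g2", "g12"): 1e-30}
    assert find_proximal(nine, universe, build_paralog_map(nine)) == {("g2", "g12")}
    ten = {("g2", "g13"): 1e-30}
    assert find_proximal(ten, universe, build_paralog_map(ten)) == set()


# ---------------------------------------------------------------------------
# colinearity chaining
# ---------------------------------------------------------------------------

def _anchors(pairs, f_chrom="chr1", o_chrom="c1"):
    return [Anchor(f"f{f}", f"o{o}", f_chrom, f, o_chrom, o, f_start=f)
            for f, o in pairs]


def test_chain_perfect_colinearity_both_orientations():
    fwd = _anchors([(i, i) for i in range(6)])
    blocks = chain_colinear_anchors(fwd, min_block_anchors=5)
    assert len(blocks) == 1 and len(blocks[0].anchors) == 6

    rev = _anchors([(i, 5 - i) for i in range(6)])
    blocks = chain_colinear_anchors(rev, min_block_anchors=5)
    assert len(blocks) == 1 and len(blocks[0].anchors) == 6


def test_chain_below_min_anchors_reports_nothing():
    blocks = chain_colinear_anchors(_anchors([(i, i) for i in range(4)]),
                                    min_block_anchors=5)
    assert blocks == []


def test_chain_respects_max_gap():
    anchors = _anchors([(0, 0), (1, 1), (2, 2), (30, 3), (31, 4), (32, 5)])
    blocks = chain_colinear_anchors(anchors, min_block_anchors=3, max_gap=25)
    assert len(blocks) == 2  # the 27-step focal jump cannot be chained
    assert sorted(len(b.anchors) for b in blocks) == [3, 3]


def test_chain_matches_exhaustive_enumeration():
    """DP chain length equals brute-force enumeration of all monotone
    chains for random anchor sets of size <= 8."""
    rnd = random.Random(4)
    for trial in range(40):
        n = rnd.randint(1, 8)
        pts = set()
        while len(pts) < n:
            pts.add((rnd.randint(0, 12), rnd.randint(0, 12)))
        pts = sorted(pts)
        max_gap = rnd.choice([2, 3, 25])
        expected = enumerate_chains(pts, max_gap)
        blocks = chain_colinear_anchors(_anchors(pts), min_block_anchors=1,
                                        max_gap=max_gap)
        assert max(len(b.anchors) for b in blocks) == expected, (pts, max_gap)


def test_anchor_used_in_at_most_one_block():
    # two interleaved colinear runs sharing no anchors
    pts = [(i, i) for i in range(6)] + [(i, 100 + i) for i in range(6)]
    blocks = chain_colinear_anchors(_anchors(pts), min_block_anchors=3, max_gap=25)
    seen = [a for b in blocks for a in b.anchors]
    assert len(seen) == len(set(seen))


# ---------------------------------------------------------------------------
# ancestral loci, transposed, epochs
# ---------------------------------------------------------------------------

def _block(ids, label):
    return ColinearBlock(("focal", label), [(f, f"o_{f}") for f in ids], float(len(ids)))


def test_ancestral_any_outgroup_rule():
    blocks = {"brassica": [], "populus": [], "vitis": [_block(["g1", "g2"], "vitis")]}
    anc = ancestral_loci(blocks, ["brassica", "populus", "vitis"])
    assert anc == {"g1", "g2"}
    assert ancestral_loci({"b": []}, ["b"]) == set()
    with pytest.raises(ValueError):
        ancestral_loci(blocks, [])


def test_find_transposed_requires_exactly_one_ancestral():
    pairs = {("g1", "g2"): 1e-30, ("g3", "g4"): 1e-30, ("g5", "g6"): 1e-30}
    anc = {"g1", "g3", "g4"}
    out = find_transposed(pairs, anc)
    assert out == {("g1", "g2"): ("g1", "g2")}  # parental=g1, transposed=g2
    # both ancestral (g3,g4) and both novel (g5,g6) are excluded


def test_assign_epochs_by_subtraction():
    recent = {("a", "b"): ("a", "b")}
    broad = {("a", "b"): ("a", "b"), ("c", "d"): ("d", "c")}
    out = assign_epochs(recent, broad)
    assert out[("a", "b")][0] is Mode.TRANSPOSED_RECENT
    assert out[("c", "d")] == (Mode.TRANSPOSED_OLD, ("d", "c"))
    assert ("e", "f") not in out


# ---------------------------------------------------------------------------
# full procedure
# ---------------------------------------------------------------------------

def test_wgd_list_precedence_over_tandem():
    """A pair named in a WGD input list keeps the WGD label even when the
    genes are consecutive in the genome."""
    genes = {f"g{i}": _gene(f"g{i}", "chr1", 100 * i) for i in range(6)}
    hits = [HomologyHit("g1", "g2", 1e-50, 100.0),
            HomologyHit("g3", "g4", 1e-50, 100.0)]
    res = classify_all(genes, hits, {"wgd_alpha": [("g1", "g2")]}, set(), {},
                       ClassifierConfig())
    modes = {p.key: p.mode for p in res.pairs}
    assert modes[("g1", "g2")] is Mode.WGD_ALPHA
    assert modes[("g3", "g4")] is Mode.TANDEM


def test_pair_in_two_wgd_lists_is_an_error():
    genes = {f"g{i}": _gene(f"g{i}", "chr1", 100 * i) for i in range(3)}
    with pytest.raises(ValueError, match="two WGD input lists"):
        classify_all(genes, [], {"wgd_alpha": [("g0", "g1")],
                                 "wgd_beta": [("g1", "g0")]},
                     set(), {}, ClassifierConfig())


def test_classify_all_modes_partition_and_order_invariance(small_sim):
    """Emitted mode sets are pairwise disjoint; output is invariant under
    permutation of input orders."""
    cfg = classifier_config(small_sim.config)
    res = classify_all(small_sim.genes, small_sim.hits, small_sim.wgd_lists,
                       small_sim.te_ids, small_sim.anchors, cfg)
    keys = [p.key for p in res.pairs]
    assert len(keys) == len(set(keys))  # one mode per pair

    rnd = random.Random(1)
    hits = list(small_sim.hits)
    rnd.shuffle(hits)
    gene_items = list(small_sim.genes.items())
    rnd.shuffle(gene_items)
    res2 = classify_all(dict(gene_items), hits, small_sim.wgd_lists,
                        small_sim.te_ids, small_sim.anchors, cfg)
    assert [(p.key, p.mode, p.parental_id) for p in res.pairs] == \
        [(p.key, p.mode, p.parental_id) for p in res2.pairs]


def test_ancestral_set_grows_with_outgroups(small_sim):
    """Monotonicity: enlarging the outgroup set can only grow the ancestral
    set (shrink the novel set)."""
    cfg = classifier_config(small_sim.config)
    res = classify_all(small_sim.genes, small_sim.hits, small_sim.wgd_lists,
                       small_sim.te_ids, small_sim.anchors, cfg)
    assert res.ancestral_broad <= res.ancestral_recent


def test_classifier_recovers_truth_labels(small_classified):
    """On simulated data the removal-order procedure recovers the true mode
    of nearly every pair (scaled-down dataset)."""
    sim, res = small_classified
    truth = {p.key: p.mode for p in sim.truth.pairs}
    pred = {p.key: p.mode for p in res.pairs}
    agree = sum(1 for k, m in truth.items() if pred.get(k) == m)
    assert agree / len(truth) >= 0.9
    # parental/transposed roles match truth for correctly-labeled pairs
    roles_pred = {p.key: p.parental_id for p in res.pairs
                  if p.mode in (Mode.TRANSPOSED_RECENT, Mode.TRANSPOSED_OLD)}
    roles_true = {p.key: p.parental_id for p in sim.truth.pairs
                  if p.mode in (Mode.TRANSPOSED_RECENT, Mode.TRANSPOSED_OLD)}
    matched = [k for k in roles_true if k in roles_pred and pred[k] == truth[k]]
    assert matched and all(roles_pred[k] == roles_true[k] for k in matched)


def test_empty_wgd_lists_yield_only_computed_modes(small_sim):
    cfg = classifier_config(small_sim.config)
    res = classify_all(small_sim.genes, small_sim.hits, {}, small_sim.te_ids,
                       small_sim.anchors, cfg)
    assert not any(p.mode in (Mode.WGD_ALPHA, Mode.WGD_BETA, Mode.WGD_GAMMA)
                   for p in res.pairs)
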