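"""Duplication-mode classification.

Assigns each candidate duplicate pair one mode — WGD (alpha/beta/gamma,
taken from input pair lists), tandem, proximal, or transposed with an epoch
— following the removal-order procedure: TE exclusion, hit filtering, WGD
label intake, tandem, proximal, then transposed via colinearity-based
ancestral-locus inference against outgroup genomes.

Transposed epochs are resolved by running the ancestral/novel test twice:
once against the full outgroup set (recent transpositions: the new copy is
colinear with no outgroup) and once against only the distant outgroups;
pairs found only in the second run predate the nearest outgroup's
divergence and are labeled old.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    ColinearBlock,
    DuplicatePair,
    GeneModel,
    HomologyHit,
    Mode,
    pair_key,
)

logger = logging.getLogger("dupstruct.classify")


@dataclass
class ClassifierConfig:
    """Thresholds of the classification procedure (defaults follow the
    standard criteria: E-value < 1e-10, top five non-self hits, fewer than
    ten non-paralogous intervening genes for proximal pairs)."""

    max_evalue: float = 1e-10
    top_n: int = 5
    max_intervening: int = 10
    min_block_anchors: int = 5
    max_gap: int = 25
    recent_outgroups: tuple[str, ...] = ()
    broad_outgroups: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# universe preparation and hit filtering
# ---------------------------------------------------------------------------

def exclude_te_and_assign_order(
    genes: Mapping[str, GeneModel], te_ids: set[str] | None = None
) -> dict[str, GeneModel]:
    """Drop TE-related genes and assign per-chromosome order indices.

    Order is by ascending start (ties by end, then gene id), 0-based within
    each chromosome; deterministic under any input ordering.
    """
    te_ids = te_ids or set()
    universe = {gid: g for gid, g in genes.items() if gid not in te_ids and not g.is_te}
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in universe.values():
        by_chrom[g.chromosome].append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(chrom_genes):
            g.order_index = i
    return universe


def filter_hits(
    hits: Iterable[HomologyHit],
    max_evalue: float = 1e-10,
    top_n: int = 5,
) -> list[HomologyHit]:
    """E-value cutoff (strict <) then per-query top-N subjects.

    Subjects are ranked by ascending E-value, ties by descending bitscore,
    then lexicographic subject id.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    by_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        if h.evalue < max_evalue:
            by_query[h.query_id].append(h)
    kept: list[HomologyHit] = []
    for q in sorted(by_query):
        ranked = sorted(by_query[q], key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        kept.extend(ranked[:top_n])
    return kept


def candidate_pairs(filtered: Iterable[HomologyHit]) -> dict[tuple[str, str], float]:
    """Unordered candidate pairs from filtered hits (union of directions),
    keyed canonically, valued by the best E-value in either direction."""
    pairs: dict[tuple[str, str], float] = {}
    for h in filtered:
        key = pair_key(h.query_id, h.subject_id)
        if key not in pairs or h.evalue < pairs[key]:
            pairs[key] = h.evalue
    return pairs


# ---------------------------------------------------------------------------
# tandem / proximal
# ---------------------------------------------------------------------------

def _order_gap(universe: Mapping[str, GeneModel], a: str, b: str) -> Optional[int]:
    ga, gb = universe.get(a), universe.get(b)
    if ga is None or gb is None or ga.chromosome != gb.chromosome:
        return None
    return abs(ga.order_index - gb.order_index)


def find_tandem(
    pairs: Mapping[tuple[str, str], float], universe: Mapping[str, GeneModel]
) -> set[tuple[str, str]]:
    """Tandem pairs: hits between consecutive genes on one chromosome."""
    return {key for key in pairs if _order_gap(universe, *key) == 1}


def build_paralog_map(pairs: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    pmap: dict[str, set[str]] = defaultdict(set)
    for a, b in pairs:
        pmap[a].add(b)
        pmap[b].add(a)
    return pmap


def find_proximal(
    pairs: Mapping[tuple[str, str], float],
    universe: Mapping[str, GeneModel],
    paralog_map: Mapping[str, set[str]],
    max_intervening: int = 10,
) -> set[tuple[str, str]]:
    """Proximal pairs: same chromosome, not adjacent (tandem is removed
    first), and fewer than ``max_intervening`` intervening genes that are
    not paralogous to either member (paralogous = connected by a filtered
    hit). Intervening paralogs do not count toward the limit."""
    by_chrom_order: dict[str, dict[int, str]] = defaultdict(dict)
    for g in universe.values():
        by_chrom_order[g.chromosome][g.order_index] = g.gene_id
    out: set[tuple[str, str]] = set()
    for (a, b) in pairs:
        ga, gb = universe.get(a), universe.get(b)
        if ga is None or gb is None or ga.chromosome != gb.chromosome:
            continue
        lo, hi = sorted((ga.order_index, gb.order_index))
        if hi - lo < 2:
            continue
        chrom = by_chrom_order[ga.chromosome]
        neigh = paralog_map.get(a, set()) | paralog_map.get(b, set())
        n_nonpar = sum(
            1 for i in range(lo + 1, hi) if chrom[i] not in neigh
        )
        if n_nonpar < max_intervening:
            out.add((a, b))
    return out


# ---------------------------------------------------------------------------
# colinearity chaining and ancestral loci
# ---------------------------------------------------------------------------

@dataclass
class Anchor:
    focal_id: str
    other_id: str
    f_chrom: str
    f_order: int
    o_chrom: str
    o_order: int
    f_start: int = 0


def chain_colinear_anchors(
    anchors: Sequence[Anchor],
    min_block_anchors: int = 5,
    max_gap: int = 25,
    genome_pair: tuple[str, str] = ("focal", "other"),
) -> list[ColinearBlock]:
    """Dynamic-programming anchor chaining into colinear blocks.

    Within one (focal chromosome, other chromosome) group, a chain extends
    anchor j to anchor i when both order-index increments are within
    [1, max_gap]; the other-genome increments must share sign along the
    chain (ascending and descending orientations are both attempted).
    Chains are extracted greedily by score (anchor count; ties by earliest
    focal start), each anchor joining at most one block; chains shorter
    than ``min_block_anchors`` are discarded.
    """
    groups: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.f_chrom, a.o_chrom)].append(a)
    blocks: list[ColinearBlock] = []
    for gkey in sorted(groups):
        group = sorted(groups[gkey], key=lambda a: (a.f_order, a.o_order, a.other_id))
        remaining = list(group)
        while True:
            chain = _best_chain(remaining, max_gap)
            if len(chain) < min_block_anchors:
                break
            blocks.append(
                ColinearBlock(
                    genome_pair=genome_pair,
                    anchors=[(a.focal_id, a.other_id) for a in chain],
                    score=float(len(chain)),
                )
            )
            used = {id(a) for a in chain}
            remaining = [a for a in remaining if id(a) not in used]
    blocks.sort(key=lambda b: (-b.score, b.anchors[0][0]))
    return blocks


def _best_chain(anchors: list[Anchor], max_gap: int) -> list[Anchor]:
    """Highest-scoring monotone chain over both orientations (DP, O(n^2))."""
    best: list[Anchor] = []
    best_key: tuple = ()
    for sign in (+1, -1):
        n = len(anchors)
        score = [1] * n
        prev = [-1] * n
        for i in range(n):
            ai = anchors[i]
            for j in range(i):
                aj = anchors[j]
                df = ai.f_order - aj.f_order
                do = sign * (ai.o_order - aj.o_order)
                if 1 <= df <= max_gap and 1 <= do <= max_gap:
                    if score[j] + 1 > score[i]:
                        score[i] = score[j] + 1
                        prev[i] = j
        if not n:
            continue
        end = max(range(n), key=lambda i: (score[i], -anchors[i].f_order))
        chain: list[Anchor] = []
        k = end
        while k != -1:
            chain.append(anchors[k])
            k = prev[k]
        chain.reverse()
        key = (len(chain), -chain[0].f_start, -chain[0].f_order)
        if len(chain) > len(best) or (len(chain) == len(best) and key > best_key):
            best = chain
            best_key = key
    return best


def anchors_from_records(
    records: Iterable[dict], universe: Mapping[str, GeneModel]
) -> list[Anchor]:
    """Attach focal coordinates/order to raw anchor records; anchors naming
    genes outside the universe (TE or unknown) are dropped."""
    out = []
    for r in records:
        g = universe.get(r["focal_id"])
        if g is None:
            continue
        out.append(Anchor(
            focal_id=g.gene_id, other_id=r["other_id"],
            f_chrom=g.chromosome, f_order=g.order_index,
            o_chrom=r["other_chromosome"], o_order=r["other_order"],
            f_start=g.start,
        ))
    return out


def ancestral_loci(
    outgroup_blocks: Mapping[str, list[ColinearBlock]],
    outgroup_set: Sequence[str],
) -> set[str]:
    """Focal genes anchored in >= 1 colinear block against >= 1 outgroup of
    the set ("any-outgroup" rule); all other focal genes are novel."""
    if not outgroup_set:
        raise ValueError("outgroup_set must not be empty")
    anc: set[str] = set()
    for label in outgroup_set:
        for block in outgroup_blocks.get(label, []):
            anc.update(f for f, _ in block.anchors)
    return anc


# ---------------------------------------------------------------------------
# transposed pairs and epochs
# ---------------------------------------------------------------------------

def find_transposed(
    pairs: Mapping[tuple[str, str], float], ancestral: set[str]
) -> dict[tuple[str, str], tuple[str, str]]:
    """Pairs joining exactly one ancestral and one novel locus.

    Returns pair key -> (parental_id, transposed_id)."""
    out: dict[tuple[str, str], tuple[str, str]] = {}
    for (a, b) in pairs:
        a_anc, b_anc = a in ancestral, b in ancestral
        if a_anc != b_anc:
            out[(a, b)] = (a, b) if a_anc else (b, a)
    return out


def assign_epochs(
    recent_set: Mapping[tuple[str, str], tuple[str, str]],
    broad_set: Mapping[tuple[str, str], tuple[str, str]],
) -> dict[tuple[str, str], tuple[Mode, tuple[str, str]]]:
    """Epoch assignment by set subtraction: pairs transposed against the
    full outgroup set are recent; pairs transposed only against the distant
    outgroups predate the nearest outgroup and are old."""
    out: dict[tuple[str, str], tuple[Mode, tuple[str, str]]] = {}
    for key, roles in recent_set.items():
        out[key] = (Mode.TRANSPOSED_RECENT, roles)
    for key, roles in broad_set.items():
        if key not in recent_set:
            out[key] = (Mode.TRANSPOSED_OLD, roles)
    return out


# ---------------------------------------------------------------------------
# full procedure
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    pairs: list[DuplicatePair]
    universe: dict[str, GeneModel]
    ancestral_recent: set[str] = field(default_factory=set)
    ancestral_broad: set[str] = field(default_factory=set)

    def by_mode(self) -> dict[Mode, list[DuplicatePair]]:
        out: dict[Mode, list[DuplicatePair]] = defaultdict(list)
        for p in self.pairs:
            out[p.mode].append(p)
        return out


def classify_all(
    genes: Mapping[str, GeneModel],
    hits: Iterable[HomologyHit],
    wgd_lists: Mapping[str, Iterable[tuple[str, str]]],
    te_ids: set[str] | None,
    outgroup_anchors: Mapping[str, Iterable[dict]],
    config: ClassifierConfig,
) -> ClassificationResult:
    """Run the whole removal-order procedure.

    ``wgd_lists`` maps a mode label (wgd_alpha/wgd_beta/wgd_gamma) to input
    pair lists; these take precedence over every computed mode. A pair
    present in two WGD lists is an input inconsistency (error).
    """
    universe = exclude_te_and_assign_order(genes, te_ids)
    known = set(universe)

    filtered = filter_hits(
        (h for h in hits if h.query_id in known and h.subject_id in known),
        max_evalue=config.max_evalue,
        top_n=config.top_n,
    )
    cand = candidate_pairs(filtered)
    paralog_map = build_paralog_map(cand)

    result_pairs: list[DuplicatePair] = []
    assigned: dict[tuple[str, str], str] = {}

    # 1. WGD label intake (input lists take precedence)
    for label in sorted(wgd_lists):
        mode = Mode(label)
        if mode not in {Mode.WGD_ALPHA, Mode.WGD_BETA, Mode.WGD_GAMMA}:
            raise ValueError(f"not a WGD mode label: {label}")
        for a, b in wgd_lists[label]:
            key = pair_key(a, b)
            if key[0] not in known or key[1] not in known:
                logger.warning("WGD pair %s references unknown/TE gene; dropped", key)
                continue
            if key in assigned:
                raise ValueError(f"pair {key} present in two WGD input lists "
                                 f"({assigned[key]} and {label})")
            assigned[key] = label
            result_pairs.append(DuplicatePair(*key, mode=mode,
                                              source_evalue=cand.get(key, float("nan"))))
    remaining = {k: v for k, v in cand.items() if k not in assigned}

    # 2. tandem
    tandem = find_tandem(remaining, universe)
    for key in sorted(tandem):
        result_pairs.append(DuplicatePair(*key, mode=Mode.TANDEM, source_evalue=remaining[key]))
    remaining = {k: v for k, v in remaining.items() if k not in tandem}

    # 3. proximal
    proximal = find_proximal(remaining, universe, paralog_map, config.max_intervening)
    for key in sorted(proximal):
        result_pairs.append(DuplicatePair(*key, mode=Mode.PROXIMAL, source_evalue=remaining[key]))
    remaining = {k: v for k, v in remaining.items() if k not in proximal}

    # 4. transposed: two outgroup runs + subtraction
    blocks: dict[str, list[ColinearBlock]] = {}
    for label in sorted(outgroup_anchors):
        anchors = anchors_from_records(outgroup_anchors[label], universe)
        blocks[label] = chain_colinear_anchors(
            anchors, config.min_block_anchors, config.max_gap,
            genome_pair=("focal", label),
        )
    anc_recent: set[str] = set()
    anc_broad: set[str] = set()
    epochs: dict[tuple[str, str], tuple[Mode, tuple[str, str]]] = {}
    if config.recent_outgroups and config.broad_outgroups:
        anc_recent = ancestral_loci(blocks, config.recent_outgroups)
        anc_broad = ancestral_loci(blocks, config.broad_outgroups)
        recent_set = find_transposed(remaining, anc_recent)
        broad_set = find_transposed(remaining, anc_broad)
        epochs = assign_epochs(recent_set, broad_set)
    for key in sorted(epochs):
        mode, (par, trans) = epochs[key]
        result_pairs.append(DuplicatePair(
            *key, mode=mode, parental_id=par, transposed_id=trans,
            source_evalue=remaining[key],
        ))
    # 5. unclassified remainder
    for key in sorted(remaining):
        if key not in epochs:
            result_pairs.append(DuplicatePair(*key, mode=Mode.UNCLASSIFIED,
                                              source_evalue=remaining[key]))

    result_pairs.sort(key=lambda p: p.key)
    return ClassificationResult(
        pairs=result_pairs,
        universe=universe,
        ancestral_recent=anc_recent,
        ancestral_broad=anc_broad,
    )
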