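"""Genome-evolution simulator with known truth labels.

Generates a focal genome (chromosomes of ordered protein-coding genes) plus
outgroup anchor sets at different divergence depths, applies duplication
events of every mode — WGD (whole-chromosome copy + fractionation, emitted
as input pair lists), tandem, proximal, and transposed with two epochs —
and evolves each duplicate pair to a target synonymous divergence with
mode-specific indel processes, so that every pipeline stage can be
exercised against ground truth without external data.

Key modeling choices
--------------------
* Substitution divergence is distance-targeted: the generator places the
  Jukes-Cantor-expected number of observed synonymous and non-synonymous
  single-base differences (at distinct codons) for the requested Ks, so a
  counting estimator with JC correction recovers ``target_ks`` by
  construction. A mechanistic per-site mutation process was deliberately
  not used: the JC correction inside NG86 is biased for 2-fold-degenerate
  sites under such a process, which would decouple the dial from the
  estimate it is meant to control.
* Epochs are expressed on the Ks time axis: a duplicate copy is present
  (anchored) in an outgroup exactly when its event's ``target_ks`` exceeds
  the outgroup's ``divergence_depth``. Old transpositions are therefore
  colinear with the nearest outgroup at their novel position and invisible
  to it as transpositions, which is what makes epoch recovery by outgroup
  subtraction well-posed.
* Indels are codon-aligned and stop-free; every simulated gene stays
  translatable. Transposed copies additionally suffer terminal truncation
  with configurable probability/fraction (the structural bias the analysis
  is designed to detect).
* Hit E-values are simulated (decreasing in divergence), not computed from
  alignments; background noise hits fall above the E-value cutoff and
  exercise the filter.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import genome_io
from .model import GeneModel, HomologyHit, Mode, SimTruth, SimTruthPair, pair_key
from .rates import _BASES, _STOPS, codon_sites, translate_codon  # codon machinery

logger = logging.getLogger("dupstruct.simulate")

_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]

EPOCH_LABELS = {
    Mode.WGD_ALPHA: "alpha",
    Mode.WGD_BETA: "beta",
    Mode.WGD_GAMMA: "gamma",
    Mode.TANDEM: "<16 Mya",
    Mode.PROXIMAL: "<16 Mya",
    Mode.TRANSPOSED_RECENT: "<16 Mya",
    Mode.TRANSPOSED_OLD: "16-107 Mya",
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EventParams:
    count: int = 0
    target_ks: float = 0.2
    indel_rate: float = 0.005  # events per amino-acid site, per copy
    indel_length_p: float = 0.4  # geometric length parameter (codons)
    omega: Optional[float] = None  # Ka/Ks of this event; None = global value


@dataclass
class OutgroupParams:
    divergence_depth: float  # substitutions per synonymous site
    rearrangement_rate: float = 0.02


@dataclass
class ExpressionParams:
    n_samples: int = 20
    base_noise: float = 0.15
    noise_coupling: float = 0.15  # extra profile noise per applied indel event


@dataclass
class FamilyParams:
    n_pairs: int = 15
    indel_multiplier: float = 3.0


@dataclass
class SimConfig:
    """Full parameterization of one simulated dataset (seed mandatory)."""

    seed: int
    n_chromosomes: int = 5
    genes_per_chromosome: int = 400
    gene_length_codons: tuple[int, int] = (120, 400)
    exon_count_range: tuple[int, int] = (1, 12)
    omega: float = 0.25  # Ka/Ks of the substitution process
    te_fraction: float = 0.04
    n_noise_hits: int = 400
    transposed_truncation_prob: float = 0.6
    transposed_truncation_fraction: float = 0.25
    outgroups: dict[str, OutgroupParams] = field(default_factory=lambda: {
        "brassica": OutgroupParams(0.45),
        "populus": OutgroupParams(1.2),
        "vitis": OutgroupParams(1.5),
    })
    recent_outgroups: tuple[str, ...] = ("brassica", "populus", "vitis")
    broad_outgroups: tuple[str, ...] = ("populus", "vitis")
    events: dict[str, EventParams] = field(default_factory=lambda: {
        "wgd_alpha": EventParams(60, 0.35, 0.0010, 0.4),
        "wgd_beta": EventParams(45, 0.80, 0.0030, 0.4),
        "wgd_gamma": EventParams(35, 1.80, 0.0060, 0.4),
        "tandem": EventParams(60, 0.15, 0.0050, 0.4),
        "proximal": EventParams(50, 0.20, 0.0130, 0.4),
        "transposed_recent": EventParams(60, 0.30, 0.0250, 0.4, omega=1.0),
        "transposed_old": EventParams(50, 0.80, 0.0250, 0.4, omega=0.8),
    })
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    family: FamilyParams = field(default_factory=FamilyParams)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, ev in self.events.items():
            if ev.count < 0 or ev.indel_rate < 0 or ev.target_ks < 0:
                raise ValueError(f"negative rate/count in event {name}")
            if not 0 < ev.indel_length_p <= 1:
                raise ValueError(f"indel_length_p of {name} must be in (0, 1]")
        for p in (self.transposed_truncation_prob, self.transposed_truncation_fraction):
            if not 0 <= p <= 1:
                raise ValueError("truncation probabilities must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "outgroups" in d:
            d["outgroups"] = {k: OutgroupParams(**v) for k, v in d["outgroups"].items()}
        if "events" in d:
            d["events"] = {k: EventParams(**v) for k, v in d["events"].items()}
        if "expression" in d:
            d["expression"] = ExpressionParams(**d["expression"])
        if "family" in d:
            d["family"] = FamilyParams(**d["family"])
        for key in ("gene_length_codons", "exon_count_range", "recent_outgroups",
                    "broad_outgroups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if seed is not None:
            d["seed"] = seed
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config(seed: int) -> SimConfig:
    """The shipped study-condition configuration (mode-graded indel rates,
    transposition truncation bias, age-graded Ks)."""
    return SimConfig(seed=seed)


# ---------------------------------------------------------------------------
# sequence-level processes
# ---------------------------------------------------------------------------

def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def _syn_neighbours(codon: str) -> list[str]:
    aa = translate_codon(codon)
    out = []
    for i, base in enumerate(codon):
        for b in _BASES:
            if b != base:
                nb = codon[:i] + b + codon[i + 1 :]
                if translate_codon(nb) == aa:
                    out.append(nb)
    return out


def _nonsyn_neighbours(codon: str) -> list[str]:
    aa = translate_codon(codon)
    out = []
    for i, base in enumerate(codon):
        for b in _BASES:
            if b != base:
                nb = codon[:i] + b + codon[i + 1 :]
                nb_aa = translate_codon(nb)
                if nb_aa is not None and nb_aa != aa:
                    out.append(nb)
    return out


_SYN_NB: dict[str, list[str]] = {c: _syn_neighbours(c) for c in _SENSE_CODONS}
_NONSYN_NB: dict[str, list[str]] = {c: _nonsyn_neighbours(c) for c in _SENSE_CODONS}


def _expected_p(d: float) -> float:
    """Observed difference proportion with JC-expected multiple hits."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def substitution_plan(
    codons: list[str], target_ks: float, omega: float, rng: np.random.Generator
) -> tuple[dict[int, str], bool]:
    """Plan single-base substitutions so that a counting estimator recovers
    ``target_ks`` (and Ka = omega * Ks).

    Synonymous then non-synonymous changes are placed at distinct codons
    first (every placed change stays observable); once distinct codons are
    exhausted — only at extreme divergence — further changes are stacked
    onto already-substituted codons at still-unchanged positions. Returns
    (codon index -> replacement codon, saturated_flag); the flag marks a
    sequence too short to host the requested divergence (best effort).
    """
    n = len(codons)
    s_total = sum(codon_sites(c)[0] for c in codons)
    n_total = 3.0 * n - s_total
    d_s = round(_expected_p(target_ks) * s_total)
    d_n = round(_expected_p(target_ks * omega) * n_total)
    cur = list(codons)
    changed: dict[int, set[int]] = {}
    saturated = False

    def _options(i: int, kind: str) -> list[tuple[int, str]]:
        aa = translate_codon(cur[i])
        opts = []
        for p in range(3):
            if p in changed.get(i, ()):
                continue
            for b in _BASES:
                if b == cur[i][p]:
                    continue
                nb = cur[i][:p] + b + cur[i][p + 1 :]
                nb_aa = translate_codon(nb)
                if nb_aa is None:
                    continue
                if (nb_aa == aa) == (kind == "syn"):
                    opts.append((p, nb))
        return opts

    def _apply(i: int, kind: str) -> bool:
        opts = _options(i, kind)
        if not opts:
            return False
        p, nb = opts[int(rng.integers(0, len(opts)))]
        cur[i] = nb
        changed.setdefault(i, set()).add(p)
        return True

    def _place(d: int, kind: str) -> None:
        nonlocal saturated
        placed = 0
        pool = [i for i in range(n) if i not in changed]
        rng.shuffle(pool)
        while placed < d and pool:
            if _apply(pool.pop(), kind):
                placed += 1
        for _round in range(2):  # stack 2nd/3rd change per codon if needed
            if placed >= d:
                break
            pool = [i for i in range(n) if len(changed.get(i, set())) < 3]
            rng.shuffle(pool)
            while placed < d and pool:
                if _apply(pool.pop(), kind):
                    placed += 1
        if placed < d:
            saturated = True

    _place(d_s, "syn")
    _place(d_n, "nonsyn")
    return {i: cur[i] for i in changed}, saturated


def apply_indels(
    codons: list[str], indel_rate: float, length_p: float, rng: np.random.Generator
) -> tuple[list[str], int]:
    """Codon-aligned indels at ``indel_rate`` events per amino-acid site,
    geometric lengths (codons); never creates stops or frame shifts.
    Returns (new codons, number of applied events)."""
    out = list(codons)
    n_events = int(rng.poisson(indel_rate * len(codons)))
    for _ in range(n_events):
        length = int(rng.geometric(length_p))
        if rng.random() < 0.5 and len(out) - length >= 10:  # deletion
            start = int(rng.integers(0, len(out) - length + 1))
            del out[start : start + length]
        else:  # insertion
            pos = int(rng.integers(0, len(out) + 1))
            ins = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), length)]
            out[pos:pos] = ins
    return out, n_events


def evolve_cds(
    cds: str,
    target_ks: float,
    indel_rate: float,
    length_p: float,
    rng: np.random.Generator,
    omega: float = 0.25,
) -> tuple[str, int, bool]:
    """Diverge one CDS to a target synonymous distance from the input.

    Substitutions first (distance-targeted, see module docstring), then
    codon-aligned indels. Returns (cds, n_indel_events, saturated_flag).
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(translate_codon(c) is None for c in codons):
        raise ValueError("internal stop codon in input CDS")
    plan, saturated = substitution_plan(codons, target_ks, omega, rng)
    codons = [plan.get(i, c) for i, c in enumerate(codons)]
    codons, n_events = apply_indels(codons, indel_rate, length_p, rng)
    return "".join(codons), n_events, saturated


def diverge_pair(
    ancestor: list[str],
    target_ks: float,
    indel_rate: float,
    length_p: float,
    omega: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str], int, int]:
    """Evolve two copies of an ancestral CDS so that their pairwise
    synonymous distance is ``target_ks`` (differences split randomly
    between the copies at distinct codons) and each copy independently
    accumulates indels. Returns (codons_a, codons_b, events_a, events_b)."""
    plan, _ = substitution_plan(ancestor, target_ks, omega, rng)
    a = list(ancestor)
    b = list(ancestor)
    for i, repl in plan.items():
        if rng.random() < 0.5:
            a[i] = repl
        else:
            b[i] = repl
    a, ev_a = apply_indels(a, indel_rate, length_p, rng)
    b, ev_b = apply_indels(b, indel_rate, length_p, rng)
    return a, b, ev_a, ev_b


def apply_transposition_bias(
    codons: list[str],
    n_exons: int,
    truncation_prob: float,
    truncation_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[str], int, float]:
    """With ``truncation_prob``, remove a terminal fraction of the
    transposed copy's CDS (codon-aligned) and reduce its exon count
    sub-proportionally (ceil, min 1), so the surviving exons are shorter
    on average. Returns (codons, n_exons, applied_fraction)."""
    if rng.random() >= truncation_prob:
        return codons, n_exons, 0.0
    n_cut = int(round(truncation_fraction * len(codons)))
    n_cut = min(n_cut, len(codons) - 10)
    if n_cut <= 0:
        return codons, n_exons, 0.0
    new_codons = codons[: len(codons) - n_cut]
    new_exons = max(1, math.ceil(n_exons * (1.0 - truncation_fraction)))
    return new_codons, new_exons, n_cut / len(codons)


def translate(codons: list[str]) -> str:
    return "".join(translate_codon(c) for c in codons)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

@dataclass
class _SimGene:
    gene_id: str
    codons: list[str]
    n_exons: int
    is_te: bool = False
    origin_age: float = math.inf  # inf = ancestral; copies carry event target_ks


@dataclass
class SimResult:
    """In-memory dataset bundle plus ground truth."""

    config: SimConfig
    genes: dict[str, GeneModel]
    hits: list[HomologyHit]
    wgd_lists: dict[str, list[tuple[str, str]]]
    te_ids: set[str]
    anchors: dict[str, list[dict]]
    expression: dict[str, list[float]]
    sample_names: list[str]
    family_ids: set[str]
    truth: SimTruth


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator; deterministic under the config's seed."""
    rng = np.random.default_rng(config.seed)
    n_chrom, n_genes = config.n_chromosomes, config.genes_per_chromosome
    lo, hi = config.gene_length_codons
    ex_lo, ex_hi = config.exon_count_range

    # ancestral genome: chrom -> ordered list of _SimGene
    chroms: dict[str, list[_SimGene]] = {}
    for c in range(1, n_chrom + 1):
        name = f"chr{c}"
        genes = []
        for i in range(n_genes):
            gid = f"{name}g{i:04d}"
            genes.append(_SimGene(
                gene_id=gid,
                codons=_random_cds(int(rng.integers(lo, hi + 1)), rng),
                n_exons=int(rng.integers(ex_lo, ex_hi + 1)),
            ))
        chroms[name] = genes

    mode_events = {Mode(k): v for k, v in config.events.items()}
    # local events reserve up to 11 ancestral positions each; cap occupancy
    # at half the genome so interval rejection-sampling stays fast
    cells_needed = 2 * mode_events.get(Mode.TANDEM, EventParams()).count + \
        11 * mode_events.get(Mode.PROXIMAL, EventParams()).count
    if cells_needed > 0.5 * n_chrom * n_genes:
        raise ValueError("tandem+proximal event counts exceed genome capacity")
    for m in (Mode.WGD_ALPHA, Mode.WGD_BETA, Mode.WGD_GAMMA):
        if mode_events.get(m, EventParams()).count > n_genes:
            raise ValueError(f"{m.value} count exceeds chromosome size")

    chrom_names = sorted(chroms)
    used_sources: set[str] = set()
    # per chromosome: ancestral indices inside tandem/proximal intervals
    blocked: dict[str, set[int]] = {c: set() for c in chrom_names}
    # planned local insertions: chrom -> list of (after_ancestral_index, copy gene)
    insertions: dict[str, list[tuple[int, _SimGene]]] = {c: [] for c in chrom_names}

    truth = SimTruth()
    pair_plans: list[dict] = []  # deferred sequence divergence work

    def _new_copy(src: _SimGene, age: float) -> _SimGene:
        return _SimGene(gene_id=src.gene_id + "d", codons=list(src.codons),
                        n_exons=src.n_exons, origin_age=age)

    def _pick_interval(span: int) -> tuple[str, int]:
        """A free ancestral interval [i, i+span] on a random chromosome."""
        for _ in range(10_000):
            chrom = chrom_names[rng.integers(0, n_chrom)]
            i = int(rng.integers(1, n_genes - span - 1))
            cells = set(range(i, i + span + 1))
            if cells & blocked[chrom]:
                continue
            if chroms[chrom][i].gene_id in used_sources:
                continue
            blocked[chrom] |= cells
            return chrom, i
        raise ValueError("event counts exceed genome capacity (no free interval)")

    # --- local duplications (tandem / proximal) ---
    for mode in (Mode.TANDEM, Mode.PROXIMAL):
        params = mode_events.get(mode)
        if params is None:
            continue
        for _ in range(params.count):
            span = 1 if mode is Mode.TANDEM else int(rng.integers(2, 11))
            chrom, i = _pick_interval(span)
            src = chroms[chrom][i]
            used_sources.add(src.gene_id)
            copy = _new_copy(src, params.target_ks)
            insertions[chrom].append((i + span - 1, copy))
            pair_plans.append(dict(mode=mode, params=params, src=src, copy=copy,
                                   parental=None))

    # --- transposed duplications ---
    for mode in (Mode.TRANSPOSED_RECENT, Mode.TRANSPOSED_OLD):
        params = mode_events.get(mode)
        if params is None:
            continue
        for _ in range(params.count):
            for _ in range(10_000):
                chrom = chrom_names[rng.integers(0, n_chrom)]
                i = int(rng.integers(0, n_genes))
                src = chroms[chrom][i]
                if src.gene_id in used_sources or i in blocked[chrom]:
                    continue
                break
            else:
                raise ValueError("no free transposed source gene")
            used_sources.add(src.gene_id)
            others = [c for c in chrom_names if c != chrom]
            tchrom = others[rng.integers(0, len(others))]
            for _ in range(10_000):
                j = int(rng.integers(1, n_genes))
                if j not in blocked[tchrom] and (j - 1) not in blocked[tchrom]:
                    break
            copy = _new_copy(src, params.target_ks)
            insertions[tchrom].append((j - 1, copy))
            pair_plans.append(dict(mode=mode, params=params, src=src, copy=copy,
                                   parental=src.gene_id))

    # --- WGDs: whole-chromosome copy + fractionation, as input lists ---
    wgd_lists: dict[str, list[tuple[str, str]]] = {}
    extra_chroms: dict[str, list[_SimGene]] = {}
    for k, mode in enumerate((Mode.WGD_ALPHA, Mode.WGD_BETA, Mode.WGD_GAMMA)):
        params = mode_events.get(mode)
        if params is None or params.count == 0:
            continue
        src_chrom = chrom_names[k % n_chrom]
        pool = [g for g in chroms[src_chrom] if g.gene_id not in used_sources]
        if len(pool) < params.count:
            raise ValueError(f"{mode.value}: not enough free genes on {src_chrom}")
        keep_idx = sorted(rng.choice(len(pool), size=params.count, replace=False))
        survivors = [pool[i] for i in keep_idx]
        new_chrom = f"{src_chrom}{mode.value.split('_')[1]}"  # e.g. chr1alpha
        extra_chroms[new_chrom] = []
        pairs = []
        for src in survivors:
            used_sources.add(src.gene_id)
            copy = _new_copy(src, params.target_ks)
            extra_chroms[new_chrom].append(copy)
            pairs.append(pair_key(src.gene_id, copy.gene_id))
            pair_plans.append(dict(mode=mode, params=params, src=src, copy=copy,
                                   parental=None))
        wgd_lists[mode.value] = sorted(pairs)

    # --- family: high-indel pairs drawn from transposed+proximal events ---
    fam_candidates = [p for p in pair_plans
                      if p["mode"] in (Mode.TRANSPOSED_RECENT, Mode.PROXIMAL)]
    n_fam = min(config.family.n_pairs, len(fam_candidates))
    fam_sel = rng.choice(len(fam_candidates), size=n_fam, replace=False) if n_fam else []
    family_ids: set[str] = set()
    for idx in sorted(fam_sel):
        plan = fam_candidates[idx]
        plan["family"] = True
        family_ids.update((plan["src"].gene_id, plan["copy"].gene_id))

    # --- sequence divergence per pair ---
    for plan in pair_plans:
        params: EventParams = plan["params"]
        src: _SimGene = plan["src"]
        copy: _SimGene = plan["copy"]
        rate = params.indel_rate * (config.family.indel_multiplier
                                    if plan.get("family") else 1.0)
        a, b, ev_a, ev_b = diverge_pair(
            src.codons, params.target_ks, rate, params.indel_length_p,
            params.omega if params.omega is not None else config.omega, rng,
        )
        trunc_frac = 0.0
        if plan["mode"] in (Mode.TRANSPOSED_RECENT, Mode.TRANSPOSED_OLD):
            b, new_exons, trunc_frac = apply_transposition_bias(
                b, copy.n_exons, config.transposed_truncation_prob,
                config.transposed_truncation_fraction, rng,
            )
            copy.n_exons = new_exons
        src.codons, copy.codons = a, b
        parental = plan["parental"]
        ga, gb = pair_key(src.gene_id, copy.gene_id)
        src_is_a = ga == src.gene_id
        truth.pairs.append(SimTruthPair(
            gene_a=ga, gene_b=gb, mode=plan["mode"],
            epoch_label=EPOCH_LABELS[plan["mode"]],
            parental_id=parental,
            transposed_id=copy.gene_id if parental else None,
            target_ks=params.target_ks,
            n_indel_events_a=ev_a if src_is_a else ev_b,
            n_indel_events_b=ev_b if src_is_a else ev_a,
            truncated_fraction=trunc_frac,
            in_family=bool(plan.get("family")),
        ))

    # --- assemble final gene order ---
    final_order: dict[str, list[_SimGene]] = {}
    for chrom in chrom_names:
        ins_by_pos: dict[int, list[_SimGene]] = {}
        for pos, g in insertions[chrom]:
            ins_by_pos.setdefault(pos, []).append(g)
        row: list[_SimGene] = []
        for i, g in enumerate(chroms[chrom]):
            row.append(g)
            row.extend(ins_by_pos.get(i, []))
        final_order[chrom] = row
    final_order.update(extra_chroms)

    # --- TE decoys: ancestral non-event genes outside local intervals ---
    te_ids: set[str] = set()
    pair_genes = {g for p in truth.pairs for g in (p.gene_a, p.gene_b)}
    te_pool = [
        g.gene_id
        for chrom in chrom_names
        for i, g in enumerate(chroms[chrom])
        if g.gene_id not in pair_genes and i not in blocked[chrom]
    ]
    n_te = int(config.te_fraction * n_chrom * n_genes)
    for idx in rng.choice(len(te_pool), size=min(n_te, len(te_pool)), replace=False):
        te_ids.add(te_pool[idx])
    for chrom in chrom_names:
        for g in chroms[chrom]:
            g.is_te = g.gene_id in te_ids

    # --- emit gene models ---
    genes: dict[str, GeneModel] = {}
    for chrom in sorted(final_order):
        for i, g in enumerate(final_order[chrom]):
            start = 1 + i * 5000
            genes[g.gene_id] = GeneModel(
                gene_id=g.gene_id, chromosome=chrom,
                start=start, end=start + 3 * len(g.codons) + 400,
                strand="+" if rng.random() < 0.5 else "-",
                n_cds_exons=g.n_exons,
                cds_seq="".join(g.codons),
                protein_seq=translate(g.codons),
                is_te=g.is_te,
            )

    # --- outgroup anchors ---
    anchors: dict[str, list[dict]] = {}
    for label in sorted(config.outgroups):
        og = config.outgroups[label]
        rows: list[dict] = []
        for chrom in sorted(final_order):
            order = 0
            for g in final_order[chrom]:
                if g.is_te or g.origin_age <= og.divergence_depth:
                    continue  # absent from this outgroup
                o_order = order
                order += 1
                u = rng.random()
                if u < og.rearrangement_rate / 2:
                    continue  # anchor lost
                if u < og.rearrangement_rate:
                    o_order = int(rng.integers(0, 10 * n_genes))  # relocated
                rows.append({
                    "focal_id": g.gene_id,
                    "other_id": f"{label}_{chrom}_{o_order:05d}",
                    "other_chromosome": chrom,
                    "other_order": o_order,
                })
                truth.gene_outgroups.setdefault(g.gene_id, set()).add(label)
        anchors[label] = rows

    # --- hits: true pairs + above-threshold noise ---
    hits: list[HomologyHit] = []
    for p in truth.pairs:
        exponent = max(15.0, 150.0 - 60.0 * p.target_ks + rng.normal(0, 5))
        evalue = 10.0 ** (-exponent)
        bits = max(60.0, 1500.0 / (1.0 + p.target_ks) + rng.normal(0, 30))
        hits.append(HomologyHit(p.gene_a, p.gene_b, evalue, round(bits, 1)))
        hits.append(HomologyHit(p.gene_b, p.gene_a, evalue, round(bits, 1)))
    all_ids = sorted(genes)
    true_keys = {p.key for p in truth.pairs}
    n_noise = 0
    while n_noise < config.n_noise_hits:
        i, j = rng.integers(0, len(all_ids), size=2)
        if i == j:
            continue
        key = pair_key(all_ids[i], all_ids[j])
        if key in true_keys:
            continue
        evalue = 10.0 ** (-float(rng.uniform(0.5, 9.3)))  # above the 1e-10 cutoff
        hits.append(HomologyHit(all_ids[i], all_ids[j], evalue,
                                round(float(rng.uniform(30, 60)), 1)))
        n_noise += 1

    # --- expression profiles ---
    ex = config.expression
    sample_names = [f"s{i:02d}" for i in range(ex.n_samples)]
    expression: dict[str, list[float]] = {}
    struct_score = {
        p.key: p.n_indel_events_a + p.n_indel_events_b + 20.0 * p.truncated_fraction
        for p in truth.pairs
    }
    for p in truth.pairs:
        base = rng.normal(5.0, 2.0, size=ex.n_samples)
        sigma = ex.base_noise + ex.noise_coupling * struct_score[p.key]
        for gid in (p.gene_a, p.gene_b):
            prof = np.maximum(0.0, base + rng.normal(0.0, sigma, size=ex.n_samples))
            expression[gid] = [float(v) for v in prof]
    for gid in all_ids:
        if gid not in expression:
            prof = np.maximum(0.0, rng.normal(5.0, 2.0, size=ex.n_samples))
            expression[gid] = [float(v) for v in prof]

    truth.pairs.sort(key=lambda p: p.key)
    return SimResult(
        config=config, genes=genes, hits=hits, wgd_lists=wgd_lists,
        te_ids=te_ids, anchors=anchors, expression=expression,
        sample_names=sample_names, family_ids=family_ids, truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle output
# ---------------------------------------------------------------------------

def write_bundle(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset bundle as plain-text files; byte-identical for a
    fixed config (same seed twice gives the same bundle)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    genome_io.write_gene_table(result.genes.values(), _p("genes.tsv"))
    genome_io.write_fasta({g.gene_id: g.cds_seq for g in result.genes.values()},
                          _p("cds.fasta"))
    genome_io.write_fasta({g.gene_id: g.protein_seq for g in result.genes.values()},
                          _p("protein.fasta"))
    with open(_p("hits.tsv"), "w") as fh:
        for h in result.hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, "90.0", "100", "10", "1",
                "1", "100", "1", "100", f"{h.evalue:.3g}", h.bitscore,
            ])) + "\n")
    for label, pairs in sorted(result.wgd_lists.items()):
        genome_io.write_pair_list(pairs, _p(f"{label}.tsv"))
    genome_io.write_id_list(result.te_ids, _p("te_genes.txt"))
    for label, rows in sorted(result.anchors.items()):
        genome_io.write_anchor_file(rows, _p(f"anchors_{label}.tsv"))
    genome_io.write_expression_matrix(result.expression, result.sample_names,
                                      _p("expression.tsv"))
    genome_io.write_id_list(result.family_ids, _p("family.txt"))

    with open(_p("truth_pairs.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\tmode\tepoch\tparental_id\ttransposed_id\t"
                 "target_ks\tn_indel_events_a\tn_indel_events_b\t"
                 "truncated_fraction\tin_family\n")
        for p in result.truth.pairs:
            fh.write("\t".join(map(str, [
                p.gene_a, p.gene_b, p.mode.value, p.epoch_label,
                p.parental_id or "", p.transposed_id or "",
                p.target_ks, p.n_indel_events_a, p.n_indel_events_b,
                f"{p.truncated_fraction:.4f}", int(p.in_family),
            ])) + "\n")
    with open(_p("truth_genes.tsv"), "w") as fh:
        fh.write("gene_id\toutgroups\n")
        for gid in sorted(result.truth.gene_outgroups):
            fh.write(f"{gid}\t{','.join(sorted(result.truth.gene_outgroups[gid]))}\n")
    return paths
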