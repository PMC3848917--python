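"""End-to-end orchestration: simulate -> classify -> structural metrics ->
rates -> expression -> statistical reports, with a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records input/output digests so identical runs can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__, genome_io, stats
from .classify import ClassificationResult, ClassifierConfig, classify_all
from .model import DuplicatePair, GeneModel, Mode
from .rates import pair_rates
from .simulate import SimConfig, simulate, write_bundle
from .structure import (
    AlignParams,
    align_pair,
    asymmetry_percentages,
    load_alignment,
    structural_metrics,
)

logger = logging.getLogger("dupstruct.pipeline")


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimConfig
    classifier: ClassifierConfig
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "BLOSUM62"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(d.get("simulation", {}) | ({"seed": seed} if seed is not None else {}))
        cls_d = d.get("classifier", {})
        cls_d.setdefault("recent_outgroups", list(sim.recent_outgroups))
        cls_d.setdefault("broad_outgroups", list(sim.broad_outgroups))
        cls_d["recent_outgroups"] = tuple(cls_d["recent_outgroups"])
        cls_d["broad_outgroups"] = tuple(cls_d["broad_outgroups"])
        classifier = ClassifierConfig(**cls_d)
        aln = d.get("alignment", {})
        return cls(
            simulation=sim,
            classifier=classifier,
            gap_open=aln.get("gap_open", 10.0),
            gap_extend=aln.get("gap_extend", 0.5),
            matrix=aln.get("matrix", "BLOSUM62"),
            alpha=d.get("alpha", 0.05),
        )

    def align_params(self) -> AlignParams:
        return AlignParams(self.gap_open, self.gap_extend, self.matrix)


def shipped_config_path(name: str = "study_conditions") -> Path:
    return Path(__file__).parent / "configs" / f"{name}.yaml"


def load_shipped_config(seed: int, name: str = "study_conditions") -> PipelineConfig:
    return PipelineConfig.from_yaml(shipped_config_path(name), seed=seed)


# ---------------------------------------------------------------------------
# metric computation
# ---------------------------------------------------------------------------

def compute_metrics(
    pairs: list[DuplicatePair],
    genes: Mapping[str, GeneModel],
    params: Optional[AlignParams] = None,
    alignments_dir: Optional[str | Path] = None,
    with_rates: bool = True,
) -> pd.DataFrame:
    """Per-pair structural-divergence measures (and NG86 rates).

    Unclassified pairs are excluded from downstream statistics and are not
    scored. Pairs with a saturated Ks get NaN there (dropped listwise by
    the correlation analyses).
    """
    rows = []
    params = params or AlignParams()
    for pair in pairs:
        if pair.mode is Mode.UNCLASSIFIED:
            continue
        ga, gb = genes.get(pair.gene_a), genes.get(pair.gene_b)
        if ga is None or gb is None:
            logger.warning("pair %s skipped: missing gene model", pair.key)
            continue
        aln = None
        if alignments_dir is not None:
            aln = load_alignment(alignments_dir, pair.gene_a, pair.gene_b)
        if aln is None:
            aln = align_pair(ga.protein_seq, gb.protein_seq, params)
        sd = structural_metrics(pair, genes, aln)
        row = {
            "gene_a": pair.gene_a, "gene_b": pair.gene_b,
            "mode": pair.mode.value,
            "parental_id": pair.parental_id, "transposed_id": pair.transposed_id,
            "d_cds_len": sd.d_cds_len, "d_avg_exon_len": sd.d_avg_exon_len,
            "n_indels": sd.n_indels, "max_indel_len": sd.max_indel_len,
            "n_indels_a": sd.n_indels_a, "n_indels_b": sd.n_indels_b,
            "max_indel_a": sd.max_indel_a, "max_indel_b": sd.max_indel_b,
        }
        if with_rates:
            try:
                est = pair_rates(aln, ga.cds_seq, gb.cds_seq)
            except ValueError as exc:
                logger.warning("pair %s rejected by rate estimation: %s", pair.key, exc)
                est = None
            row.update({
                "ka": est.ka if est else None,
                "ks": est.ks if est else None,
                "omega": est.omega if est else None,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def struct_div_records(metrics: pd.DataFrame):
    """Reconstruct (DuplicatePair, StructDiv) records from a metric table
    (for the asymmetry analysis)."""
    from .model import StructDiv

    out = []
    for r in metrics.itertuples(index=False):
        pair = DuplicatePair(
            gene_a=r.gene_a, gene_b=r.gene_b, mode=Mode(r.mode),
            parental_id=r.parental_id or None, transposed_id=r.transposed_id or None,
        )
        sd = StructDiv(
            d_cds_len=int(r.d_cds_len), d_avg_exon_len=float(r.d_avg_exon_len),
            n_indels=int(r.n_indels), max_indel_len=int(r.max_indel_len),
            n_indels_a=int(r.n_indels_a), n_indels_b=int(r.n_indels_b),
            max_indel_a=int(r.max_indel_a), max_indel_b=int(r.max_indel_b),
        )
        out.append((pair, sd))
    return out


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order, fail fast, write outputs + manifest.

    Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.simulation.seed,
        "config": {
            "simulation": config.simulation.to_dict(),
            "classifier": dataclasses.asdict(config.classifier),
            "alignment": {"gap_open": config.gap_open, "gap_extend": config.gap_extend,
                          "matrix": config.matrix},
            "alpha": config.alpha,
        },
        "stages": {},
    }

    # stage 1: simulate
    sim = simulate(config.simulation)
    bundle_dir = out / "bundle"
    paths = write_bundle(sim, bundle_dir)
    manifest["stages"]["simulate"] = {
        "n_genes": len(sim.genes), "n_true_pairs": len(sim.truth.pairs),
        "inputs": {name: _digest(p) for name, p in sorted(paths.items())},
    }

    # stage 2: classify (from the written files, exercising the readers)
    genes = genome_io.read_gene_models(paths["genes.tsv"], fmt="table")
    genome_io.attach_sequences(genes, paths["cds.fasta"], paths["protein.fasta"])
    hits = genome_io.read_hits(paths["hits.tsv"])
    te_ids = genome_io.read_id_list(paths["te_genes.txt"])
    wgd_lists = {
        label: genome_io.read_pair_list(paths[f"{label}.tsv"], set(genes))
        for label in sim.wgd_lists
    }
    anchors = {
        label: genome_io.read_anchor_file(paths[f"anchors_{label}.tsv"])
        for label in sim.anchors
    }
    result = classify_all(genes, hits, wgd_lists, te_ids, anchors, config.classifier)
    genome_io.write_pairs_tsv(result.pairs, out / "pairs.tsv")
    by_mode = {m.value: len(ps) for m, ps in sorted(result.by_mode().items())}
    manifest["stages"]["classify"] = {"pairs_by_mode": by_mode}

    # stage 3+4: structural metrics and rates
    metrics = compute_metrics(result.pairs, genes, config.align_params())
    metrics_out = metrics.copy()
    metrics_out.to_csv(out / "metrics.tsv", sep="\t", index=False)
    manifest["stages"]["metrics"] = {"n_pairs": len(metrics)}

    # stage 5: expression divergence
    profiles = genome_io.read_expression_matrix(paths["expression.tsv"])
    metrics = stats.attach_expression_divergence(metrics, profiles)

    # stage 6: reports
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    mode_rep = stats.mode_contrast_report(metrics)
    mode_rep.medians.to_csv(report_dir / "mode_medians.tsv", sep="\t")
    mode_rep.tests.to_csv(report_dir / "mode_contrasts.tsv", sep="\t", index=False)
    wgd_rep, tr_rep, ka_rep = stats.epoch_contrast_report(metrics)
    wgd_rep.tests.to_csv(report_dir / "epoch_wgd_contrasts.tsv", sep="\t", index=False)
    tr_rep.tests.to_csv(report_dir / "epoch_transposed_contrasts.tsv", sep="\t", index=False)
    if ka_rep is not None:
        ka_rep.tests.to_csv(report_dir / "epoch_ka_contrasts.tsv", sep="\t", index=False)
    corr_rates = stats.structure_value_correlations(metrics, ["ka", "ks", "omega"])
    corr_rates.to_csv(report_dir / "correlations_rates.tsv", sep="\t", index=False)
    corr_expr = stats.structure_value_correlations(metrics, ["expr_div"])
    corr_expr.to_csv(report_dir / "correlations_expression.tsv", sep="\t", index=False)
    family_ids = genome_io.read_id_list(paths["family.txt"])
    fam = stats.family_comparison(family_ids, metrics)
    fam.to_csv(report_dir / "family_test.tsv", sep="\t", index=False)
    asym = asymmetry_percentages(struct_div_records(metrics), genes)
    pd.DataFrame(asym).T.rename_axis("feature").to_csv(
        report_dir / "asymmetry.tsv", sep="\t")
    manifest["stages"]["report"] = {
        "mode_orderings": mode_rep.orderings,
        "outputs": {p.name: _digest(p) for p in sorted(report_dir.iterdir())},
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
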