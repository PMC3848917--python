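"""Expression divergence and the comparative statistics of the pipeline.

Expression divergence between two duplicates is 1 - r, the complement of
the Pearson correlation of their expression profiles across samples.
Mode and epoch contrasts use two-sided Wilcoxon rank-sum tests between
consecutive groups; structure-rate and structure-expression relationships
use Pearson correlation with the t-transform p-value; the gene-family
contrast uses Welch's unequal-variance t-test. Raw p-values are reported
at alpha = 0.05 with no multiple-testing adjustment.

Pairs with undefined members (saturated Ks, zero-variance expression) are
dropped listwise per analysis, with counts logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ExpressionProfile, Mode, TestResult

logger = logging.getLogger("dupstruct.stats")

#: the four headline structural-divergence measures, as metric-table columns
MEASURES = ("d_cds_len", "d_avg_exon_len", "n_indels", "max_indel_len")

EXACT_THRESHOLD = 8


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def expression_divergence(p1: ExpressionProfile, p2: ExpressionProfile) -> Optional[float]:
    """1 - Pearson r between two expression profiles; None if undefined.

    Undefined when either profile has zero variance. Profiles must have
    equal length >= 3.
    """
    x = np.asarray(p1.values, dtype=float)
    y = np.asarray(p2.values, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"profile length mismatch ({len(x)} vs {len(y)})")
    if len(x) < 3:
        raise ValueError("expression profiles need >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("zero-variance expression profile (%s/%s); divergence undefined",
                    p1.gene_id, p2.gene_id)
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration when both samples are small (max n <= 8) and
    tie-free; otherwise normal approximation with tie-corrected variance
    and continuity correction. The reported statistic is the rank sum of
    ``x`` (midranks for ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(
            statistic=float(sps.rankdata(pooled)[: len(x)].sum()),
            p_value=1.0, method="wilcoxon_normal",
            n_x=len(x), n_y=len(y), direction=0, degenerate=True,
        )
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = tie_free and max(len(x), len(y)) <= EXACT_THRESHOLD
    res = sps.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u = float(res.statistic)
    w = u + len(x) * (len(x) + 1) / 2.0
    direction = int(np.sign(u - len(x) * len(y) / 2.0))
    return TestResult(
        statistic=w, p_value=float(res.pvalue),
        method="wilcoxon_exact" if exact else "wilcoxon_normal",
        n_x=len(x), n_y=len(y), direction=direction,
    )


def pearson_correlation_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with the two-sided t-transform p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a correlated vector")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(r), p_value=float(p), method="pearson_t",
        n_x=len(x), n_y=len(y), direction=int(np.sign(r)),
    )


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        t = 0.0 if x.mean() == y.mean() else math.inf * np.sign(x.mean() - y.mean())
        return TestResult(statistic=float(t),
                          p_value=1.0 if t == 0 else 0.0, method="welch_t",
                          n_x=len(x), n_y=len(y),
                          direction=int(np.sign(t)), degenerate=True)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(t), p_value=float(p), method="welch_t",
        n_x=len(x), n_y=len(y), direction=int(np.sign(t)),
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ContrastReport:
    """Per-measure group medians, consecutive-group tests, and ordering."""

    group_order: list[str]
    medians: pd.DataFrame  # index: measure, columns: group labels
    tests: pd.DataFrame  # columns: measure, group_lo, group_hi, statistic, p_value, n_lo, n_hi
    orderings: dict[str, str] = field(default_factory=dict)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return self.medians, self.tests


def _contrast(
    metrics: pd.DataFrame,
    group_col: str,
    group_order: Sequence[str],
    measures: Sequence[str],
    alternative: str = "two-sided",
) -> ContrastReport:
    present = [g for g in group_order if (metrics[group_col] == g).sum() > 0]
    skipped = [g for g in group_order if g not in present]
    if skipped:
        logger.warning("contrast groups with no pairs skipped: %s", skipped)
    medians = pd.DataFrame(index=list(measures), columns=present, dtype=float)
    rows = []
    orderings: dict[str, str] = {}
    for measure in measures:
        groups = {
            g: metrics.loc[metrics[group_col] == g, measure].dropna().to_numpy()
            for g in present
        }
        for g in present:
            medians.loc[measure, g] = float(np.median(groups[g])) if len(groups[g]) else float("nan")
        for lo, hi in zip(present[:-1], present[1:]):
            if len(groups[lo]) < 2 or len(groups[hi]) < 2:
                logger.warning("contrast %s vs %s skipped for %s (<2 pairs)", lo, hi, measure)
                continue
            res = wilcoxon_rank_sum(groups[lo], groups[hi], alternative=alternative)
            rows.append({
                "measure": measure, "group_lo": lo, "group_hi": hi,
                "statistic": res.statistic, "p_value": res.p_value,
                "n_lo": res.n_x, "n_hi": res.n_y, "method": res.method,
            })
        med = medians.loc[measure, present].astype(float)
        orderings[measure] = " < ".join(
            med.sort_values(kind="stable").index.tolist()
        )
    tests = pd.DataFrame(
        rows, columns=["measure", "group_lo", "group_hi", "statistic",
                       "p_value", "n_lo", "n_hi", "method"],
    )
    return ContrastReport(group_order=present, medians=medians,
                          tests=tests, orderings=orderings)


#: group order for the recent-duplicates mode comparison
MODE_ORDER = (Mode.WGD_ALPHA.value, Mode.TANDEM.value, Mode.PROXIMAL.value,
              Mode.TRANSPOSED_RECENT.value)

#: five-group order of the Ka epoch comparison
KA_EPOCH_ORDER = (Mode.WGD_ALPHA.value, Mode.WGD_BETA.value,
                  Mode.TRANSPOSED_RECENT.value, Mode.WGD_GAMMA.value,
                  Mode.TRANSPOSED_OLD.value)


def mode_contrast_report(
    metrics: pd.DataFrame, alternative: str = "two-sided"
) -> ContrastReport:
    """Structural divergence across duplication modes, restricted to the
    age-comparable groups: WGD limited to the youngest (alpha) event and
    transposed pairs to the recent epoch.

    ``metrics`` needs a ``mode`` column plus the four measure columns.
    """
    sub = metrics[metrics["mode"].isin(MODE_ORDER)]
    return _contrast(sub, "mode", MODE_ORDER, MEASURES, alternative)


def epoch_contrast_report(
    metrics: pd.DataFrame, alternative: str = "two-sided"
) -> tuple[ContrastReport, ContrastReport, Optional[ContrastReport]]:
    """Structural divergence across duplication epochs.

    Returns three reports: WGD alpha/beta/gamma, transposed recent/old,
    and (when a ``ka`` column is present) the five-group Ka comparison.
    """
    wgd = _contrast(
        metrics[metrics["mode"].isin([m.value for m in
                                      (Mode.WGD_ALPHA, Mode.WGD_BETA, Mode.WGD_GAMMA)])],
        "mode",
        (Mode.WGD_ALPHA.value, Mode.WGD_BETA.value, Mode.WGD_GAMMA.value),
        MEASURES, alternative,
    )
    transposed = _contrast(
        metrics[metrics["mode"].isin([m.value for m in
                                      (Mode.TRANSPOSED_RECENT, Mode.TRANSPOSED_OLD)])],
        "mode",
        (Mode.TRANSPOSED_RECENT.value, Mode.TRANSPOSED_OLD.value),
        MEASURES, alternative,
    )
    ka_report = None
    if "ka" in metrics.columns:
        ka_report = _contrast(
            metrics[metrics["mode"].isin(KA_EPOCH_ORDER)],
            "mode", KA_EPOCH_ORDER, ("ka",), alternative,
        )
    return wgd, transposed, ka_report


def structure_value_correlations(
    metrics: pd.DataFrame, value_cols: Sequence[str]
) -> pd.DataFrame:
    """Pearson correlations of each structural measure against each value
    column (e.g. ka/ks/omega or expression divergence), pairs with
    undefined values dropped listwise per cell."""
    rows = []
    for measure in MEASURES:
        for col in value_cols:
            sub = metrics[[measure, col]].dropna()
            n_dropped = len(metrics) - len(sub)
            if n_dropped:
                logger.info("correlation %s~%s: %d pairs dropped (undefined)",
                            measure, col, n_dropped)
            if len(sub) < 3 or sub[measure].nunique() < 2 or sub[col].nunique() < 2:
                rows.append({"measure": measure, "value": col, "r": float("nan"),
                             "p_value": float("nan"), "n": len(sub)})
                continue
            res = pearson_correlation_test(sub[measure], sub[col])
            rows.append({"measure": measure, "value": col, "r": res.statistic,
                         "p_value": res.p_value, "n": res.n_x})
    return pd.DataFrame(rows)


def family_comparison(
    family_ids: set[str], metrics: pd.DataFrame
) -> pd.DataFrame:
    """Per-measure Welch t-test of family pairs against all pairs.

    A pair belongs to the family when either member is in ``family_ids``
    (configurable upstream); the population is the full pair set, family
    included.
    """
    if not family_ids:
        raise ValueError("empty family id set")
    in_family = metrics["gene_a"].isin(family_ids) | metrics["gene_b"].isin(family_ids)
    if in_family.sum() < 2:
        raise ValueError("fewer than 2 family pairs")
    rows = []
    for measure in MEASURES:
        fam = metrics.loc[in_family, measure].dropna().to_numpy()
        pop = metrics[measure].dropna().to_numpy()
        res = welch_t_test(fam, pop)
        rows.append({
            "measure": measure,
            "family_mean": float(np.mean(fam)),
            "population_mean": float(np.mean(pop)),
            "t": res.statistic, "p_value": res.p_value,
            "n_family": len(fam), "n_population": len(pop),
        })
    return pd.DataFrame(rows)


def attach_expression_divergence(
    metrics: pd.DataFrame, profiles: dict[str, ExpressionProfile]
) -> pd.DataFrame:
    """Add an ``expr_div`` (1 - r) column; pairs with a missing profile or
    undefined divergence get NaN (excluded listwise downstream)."""
    vals = []
    n_missing = 0
    for row in metrics.itertuples(index=False):
        pa, pb = profiles.get(row.gene_a), profiles.get(row.gene_b)
        if pa is None or pb is None:
            n_missing += 1
            vals.append(float("nan"))
            continue
        d = expression_divergence(pa, pb)
        vals.append(float("nan") if d is None else d)
    if n_missing:
        logger.info("%d pairs lack an expression profile; excluded there", n_missing)
    out = metrics.copy()
    out["expr_div"] = vals
    return out
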