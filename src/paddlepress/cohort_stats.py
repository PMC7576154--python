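"""Species-level summaries and comparative statistics.

A cohort table is tidy: one row per (species, individual, metric, value).
Comparative statistics follow the classical one-way ANOVA decomposition
and Holm-Sidak step-down correction for pairwise comparisons.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InvalidParameterError, MissingMetricError

REQUIRED_COLUMNS = ("species", "individual", "metric", "value")


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy cohort-table contract; warns (via the returned
    attrs) on unbalanced designs rather than failing."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise InvalidParameterError(f"cohort table missing column '{col}'")
    if table.duplicated(subset=["species", "individual", "metric"]).any():
        raise InvalidParameterError("duplicate (species, individual, metric) rows")
    if not np.isfinite(table["value"]).all():
        raise InvalidParameterError("cohort values must be finite")
    counts = table.groupby(["metric", "species"], sort=False).size()
    balanced = bool(counts.groupby(level="metric").nunique().eq(1).all())
    out = table.copy()
    out.attrs["balanced"] = balanced
    return out


def summarize(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-species mean, sample sd (n-1) and n, plus a pooled grand row."""
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise MissingMetricError(f"metric '{metric}' not in cohort table")
    rows = [
        {
            "species": sp,
            "mean": float(g["value"].mean()),
            "sd": float(g["value"].std(ddof=1)) if len(g) > 1 else 0.0,
            "n": int(len(g)),
        }
        for sp, g in sub.groupby("species", sort=False)
    ]
    rows.append(
        {
            "species": "__grand__",
            "mean": float(sub["value"].mean()),
            "sd": float(sub["value"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "n": int(len(sub)),
        }
    )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical decomposition F = (SSB/(k-1)) / (SSW/(n-k)); the p-value
    is the upper tail of the F(k-1, n-k) distribution.

    Zero between- and within-group variance is flagged degenerate with
    F = 0 rather than raising."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise InvalidParameterError("need at least 2 groups")
    ns = np.array([len(g) for g in gs])
    if (ns < 1).any() or (ns < 2).all():
        raise InvalidParameterError("need >= 1 value per group and >= 2 in one group")
    n = int(ns.sum())
    grand = float(np.concatenate(gs).mean())
    means = np.array([g.mean() for g in gs])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    dfb, dfw = k - 1, n - k
    if ssw == 0 and ssb == 0:
        return AnovaResult(0.0, dfb, dfw, 1.0, degenerate=True)
    if ssw == 0:
        return AnovaResult(float("inf"), dfb, dfw, 0.0)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sstats.f.sf(f, dfb, dfw))
    return AnovaResult(f, dfb, dfw, p)


def holm_sidak(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down adjustment.

    Sorted ascending, adjusted p_(i) = 1 - (1 - p_(i))^(m - i + 1), made
    monotone non-decreasing with a running maximum; rejection proceeds
    while the adjusted p stays below alpha. Returns (adjusted, reject) in
    the input order; empty input yields empty output."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise InvalidParameterError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adj_sorted[i] < alpha:
            reject_sorted[i] = True
        else:
            break
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adj_sorted
    reject[order] = reject_sorted
    return adjusted, reject


def pairwise_p_values(
    table: pd.DataFrame,
    metric: str,
    method: str = "ttest",
    paired_on: str | None = None,
) -> pd.DataFrame:
    """Raw p-values for all species pairs on one metric.

    ``method``: 'ttest' (Welch), 'mannwhitney', or with ``paired_on`` set
    (e.g. pairing individuals) 'ttest' becomes a paired t-test and
    'wilcoxon' a signed-rank test."""
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise MissingMetricError(f"metric '{metric}' not in cohort table")
    species = list(dict.fromkeys(sub["species"]))
    rows = []
    for a, b in itertools.combinations(species, 2):
        xa = sub[sub["species"] == a]
        xb = sub[sub["species"] == b]
        if paired_on is not None:
            merged = xa.merge(xb, on=paired_on, suffixes=("_a", "_b"))
            va, vb = merged["value_a"].to_numpy(), merged["value_b"].to_numpy()
            if method == "wilcoxon":
                p = float(sstats.wilcoxon(va, vb).pvalue)
            else:
                p = float(sstats.ttest_rel(va, vb).pvalue)
        else:
            va, vb = xa["value"].to_numpy(), xb["value"].to_numpy()
            if method == "mannwhitney":
                p = float(sstats.mannwhitneyu(va, vb).pvalue)
            else:
                p = float(sstats.ttest_ind(va, vb, equal_var=False).pvalue)
        rows.append({"group_a": a, "group_b": b, "p_raw": p})
    return pd.DataFrame(rows)
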