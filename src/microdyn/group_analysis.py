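"""Two-group nonparametric comparison of microstate indicators.

Per-class duration/coverage/occurrence and per-cell syntax probabilities
are compared between two cohorts with Wilcoxon rank-sum tests;
Benjamini-Hochberg FDR is applied within each indicator's family of
class-wise tests (and across all off-diagonal cells for the syntax
matrix). Both raw and adjusted p-values are always reported.
Shapiro-Wilk normality p-values annotate, but never gate, the
nonparametric pipeline. A Table-1-style cohort summary (counts with
percentages, mean (SD), between-group p) is also provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "shapiro_wilk",
    "wilcoxon_ranksum",
    "fdr_bh",
    "compare_cohorts",
    "compare_syntax",
    "summarize_cohort",
    "INDICATORS",
]

INDICATORS = ("duration_ms", "coverage", "occurrence")


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (annotation only, 3 <= n <= 5000)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if v.size > 5000:
        raise ValueError("Shapiro-Wilk p-values are unreliable above n=5000")
    if np.ptp(v) == 0:
        raise ValueError("zero-variance sample: W undefined")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_ranksum(a, b, exact_threshold: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples have <= ``exact_threshold``
    observations and no ties are present; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= exact_threshold and b.size <= exact_threshold and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_frames(stats_table: pd.DataFrame) -> tuple[str, str]:
    groups = sorted(stats_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    for g in groups:
        n = stats_table.loc[stats_table.group == g, "scan_id"].nunique()
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 scans")
    return groups[0], groups[1]


def compare_cohorts(
    stats_table: pd.DataFrame, alpha: float = 0.05, exact_threshold: int = 10
) -> pd.DataFrame:
    """Class-wise Wilcoxon comparison of every indicator, FDR per family.

    ``stats_table`` is the tidy per-scan table with columns
    scan_id, group, class, duration_ms, coverage, occurrence. Each
    indicator forms its own FDR family of k class-wise tests. Returns a
    tidy frame with group means/SDs/medians, raw and adjusted p, and
    significance flags at ``alpha``.
    """
    required = {"scan_id", "group", "class"} | set(INDICATORS)
    missing = required - set(stats_table.columns)
    if missing:
        raise ValueError(f"stats table missing columns {sorted(missing)}")
    g1, g2 = _group_frames(stats_table)
    rows = []
    for indicator in INDICATORS:
        for cls, sub in stats_table.groupby("class"):
            a = sub.loc[sub.group == g1, indicator].dropna().to_numpy()
            b = sub.loc[sub.group == g2, indicator].dropna().to_numpy()
            p = wilcoxon_ranksum(a, b, exact_threshold=exact_threshold)
            try:
                sw_p = min(shapiro_wilk(a)[1], shapiro_wilk(b)[1])
            except ValueError:
                sw_p = np.nan
            rows.append(
                {
                    "indicator": indicator,
                    "class": cls,
                    "family": indicator,
                    f"median_{g1}": float(np.median(a)),
                    f"median_{g2}": float(np.median(b)),
                    f"mean_{g1}": float(a.mean()),
                    f"mean_{g2}": float(b.mean()),
                    f"sd_{g1}": float(a.std(ddof=1)),
                    f"sd_{g2}": float(b.std(ddof=1)),
                    "shapiro_p_min": sw_p,
                    "p_raw": p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_fdr"] = np.nan
    for indicator in INDICATORS:
        mask = df.indicator == indicator
        df.loc[mask, "p_fdr"] = fdr_bh(df.loc[mask, "p_raw"].to_numpy())
    df["significant_raw"] = df.p_raw < alpha
    df["significant_fdr"] = df.p_fdr < alpha
    return df


def compare_syntax(
    syntax_g1: np.ndarray, syntax_g2: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Cell-wise Wilcoxon on per-scan syntax matrices, FDR across all cells.

    Inputs are stacked per-scan probability matrices of shape
    (n_scans, k, k); the k(k-1) off-diagonal cells form one FDR family.
    """
    A = np.asarray(syntax_g1, dtype=float)
    B = np.asarray(syntax_g2, dtype=float)
    if A.ndim != 3 or B.ndim != 3 or A.shape[1:] != B.shape[1:]:
        raise ValueError("need (n_scans, k, k) stacks with matching k")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 scans per group")
    k = A.shape[1]
    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            p = wilcoxon_ranksum(A[:, i, j], B[:, i, j])
            rows.append(
                {
                    "from_state": i,
                    "to_state": j,
                    "mean_g1": float(A[:, i, j].mean()),
                    "mean_g2": float(B[:, i, j].mean()),
                    "p_raw": p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_bh(df["p_raw"].to_numpy())
    df["significant_raw"] = df.p_raw < alpha
    df["significant_fdr"] = df.p_fdr < alpha
    return df


# --------------------------------------------------------------------------
# Table-1-style cohort summary
# --------------------------------------------------------------------------

_CATEGORICAL = ("sex", "etiology")
_CONTINUOUS = ("age", "post_injury_months")


def _categorical_p(sub: pd.DataFrame, var: str) -> float:
    table = pd.crosstab(sub[var], sub["group"]).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    chi2 = sps.chi2_contingency(table)
    expected = chi2.expected_freq
    if table.shape == (2, 2) and (expected < 5).any():
        return float(sps.fisher_exact(table)[1])
    return float(chi2.pvalue)


def summarize_cohort(
    demographics: pd.DataFrame, continuous_test: str = "welch"
) -> pd.DataFrame:
    """Cohort characteristics by group, with between-group p-values.

    Expects columns scan_id, group, sex, age, etiology,
    post_injury_months. Categorical variables are summarised as
    ``count (percent)`` with a chi-square p (Fisher exact for 2x2 tables
    with an expected cell below 5); continuous ones as ``mean (SD)``
    with a Welch t-test by default (``continuous_test="wilcoxon"``
    switches to the rank-sum test). Percentages are rounded to one
    decimal, as are SDs.
    """
    df = demographics.copy()
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    if continuous_test not in ("welch", "wilcoxon"):
        raise ValueError("continuous_test must be 'welch' or 'wilcoxon'")
    cols = ["ALL", *groups]
    rows = []

    def fmt_count(n, total):
        pct = 100.0 * n / total if total else 0.0
        return f"{n} ({pct:.1f}%)"

    n_all = len(df)
    n_by = {g: int((df.group == g).sum()) for g in groups}
    rows.append({"variable": "N", "level": "", "ALL": str(n_all),
                 **{g: str(n_by[g]) for g in groups}, "p": np.nan})

    for var in _CATEGORICAL:
        if var not in df.columns:
            continue
        p = _categorical_p(df, var)
        rows.append({"variable": var, "level": "", "ALL": "", **{g: "" for g in groups}, "p": p})
        if isinstance(df[var].dtype, pd.CategoricalDtype):
            levels = list(df[var].cat.categories)  # keep declared empty levels
        else:
            levels = sorted(df[var].dropna().unique())
        for level in levels:
            entry = {"variable": var, "level": str(level), "p": np.nan}
            entry["ALL"] = fmt_count(int((df[var] == level).sum()), n_all)
            for g in groups:
                sub = df[df.group == g]
                entry[g] = fmt_count(int((sub[var] == level).sum()), len(sub))
            rows.append(entry)

    for var in _CONTINUOUS:
        if var not in df.columns:
            continue
        a = df.loc[df.group == groups[0], var].dropna().to_numpy(dtype=float)
        b = df.loc[df.group == groups[1], var].dropna().to_numpy(dtype=float)
        if continuous_test == "welch":
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = wilcoxon_ranksum(a, b)
        entry = {"variable": var, "level": "", "p": p}
        for name, vals in (("ALL", df[var].dropna()), (groups[0], a), (groups[1], b)):
            vals = np.asarray(vals, dtype=float)
            entry[name] = f"{vals.mean():.3g} ({vals.std(ddof=1):.3g})"
        rows.append(entry)

    out = pd.DataFrame(rows, columns=["variable", "level", *cols, "p"])
    return out
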