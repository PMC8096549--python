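"""Demographic/clinical group tests and NH-clinical correlations.

Covers the summary-table statistics (one-way ANOVA with LSD post hocs
reconstructed from means/SDs/ns, pooled two-sample t from summaries, Pearson
chi-square on contingency counts), raw-data equivalents, Pearson correlations
between cluster NH and clinical scores, and Benjamini-Hochberg step-up
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "CorrelationResult",
    "anova_from_summary",
    "anova_raw",
    "ttest_from_summary",
    "chi_square_table",
    "pearson_corr",
    "bh_adjust",
    "nh_clinical_correlations",
    "summary_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and n of one variable in one group (a printed-table cell)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df: tuple[int, int]
    lsd_t: dict[tuple[int, int], float]
    lsd_p: dict[tuple[int, int], float]


@dataclass(frozen=True)
class CorrelationResult:
    cluster: str
    score: str
    r: float
    p_raw: float
    p_bh: float
    n: int


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA F reconstructed from per-group mean/SD/n, with LSD
    pairwise t-tests on the pooled within-group mean square."""
    k = len(summaries)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_tot = ns.sum()
    grand = (ns * means).sum() / n_tot
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(n_tot) - k
    if ssw == 0:
        if ssb > 0:
            return AnovaResult(np.inf, 0.0, (df1, df2), {}, {})
        return AnovaResult(0.0, 1.0, (df1, df2), {}, {})
    mse = ssw / df2
    f = (ssb / df1) / mse
    p = float(stats.f.sf(f, df1, df2))
    lsd_t, lsd_p = {}, {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
            t = (means[i] - means[j]) / se
            lsd_t[(i, j)] = float(t)
            lsd_p[(i, j)] = float(2 * stats.t.sf(abs(t), df2))
    return AnovaResult(float(f), p, (df1, df2), lsd_t, lsd_p)


def anova_raw(groups: list[np.ndarray]) -> AnovaResult:
    """One-way ANOVA on raw samples, via the summary-statistic route (the two
    are algebraically identical)."""
    summaries = [
        GroupSummary(float(np.mean(g)), float(np.std(g, ddof=1)), len(g)) for g in groups
    ]
    return anova_from_summary(summaries)


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t (two-tailed) from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        raise ZeroDivisionError("zero variance in both groups with unequal means")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(2 * stats.t.sf(abs(t), df))


def chi_square_table(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if (expected <= 0).any():
        raise ValueError("zero expected count")
    return float(chi2), int(df), float(p)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Sample Pearson r with two-tailed t-based p on pairwise-complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved:
    p~_(i) = min_{j >= i} (p_(j) * m / j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def nh_clinical_correlations(
    cluster_nh: pd.DataFrame,
    scores: pd.DataFrame,
    score_names: list[str],
) -> list[CorrelationResult]:
    """Pearson correlations between each cluster's mean NH and each clinical
    score, BH-adjusted per score across the cluster family (the family is the
    set of abnormal clusters the score is tested against)."""
    results: list[CorrelationResult] = []
    for score in score_names:
        fam: list[tuple[str, float, float, int]] = []
        for cluster in cluster_nh.columns:
            try:
                r, p, n = pearson_corr(cluster_nh[cluster].to_numpy(), scores[score].to_numpy())
            except ValueError:
                continue
            fam.append((cluster, r, p, n))
        if not fam:
            continue
        p_bh = bh_adjust([f[2] for f in fam])
        for (cluster, r, p, n), pb in zip(fam, p_bh):
            results.append(CorrelationResult(cluster, score, r, p, float(pb), n))
    return results


def summary_table(table: pd.DataFrame, variables: list[str], group_col: str = "group") -> pd.DataFrame:
    """Per-group mean +/- SD plus the omnibus test, one row per variable.

    Variables observed in all three groups get the ANOVA F; patient-only
    variables (controls all-missing) get the pooled two-sample t between the
    two patient groups.
    """
    groups = list(dict.fromkeys(table[group_col]))
    rows = []
    for var in variables:
        by = [table.loc[table[group_col] == g, var].dropna().to_numpy() for g in groups]
        cells = {
            g: (f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" if len(v) else "")
            for g, v in zip(groups, by)
        }
        present = [v for v in by if len(v) >= 2]
        if len(present) >= 3:
            res = anova_raw(present)
            stat, p, kind = res.f, res.p, "F"
        elif len(present) == 2:
            a, b = present
            stat, p = ttest_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            kind = "t"
        else:
            stat, p, kind = np.nan, np.nan, ""
        rows.append({"variable": var, **cells, "stat": stat, "stat_type": kind, "p": p})
    return pd.DataFrame(rows)
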