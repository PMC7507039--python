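"""Two-sample and contingency-table statistics for small clinical cohorts.

The workflow mirrors a standard SPSS-style analysis of a small aetiology
cohort: continuous variables are tested for normality (Shapiro-Wilk), then
compared with a pooled or Welch two-sample t-test (Welch when Levene's
test rejects equal variances) or with Wilcoxon's rank-sum test; boolean
risk factors are compared with a Pearson chi-square test on the
contingency table (no continuity correction), with Fisher's exact p
reported alongside for small tables.

All tests return a :class:`StatResult` carrying the statistic, degrees of
freedom where defined, the two-sided p-value, an effect summary and
free-text notes. Computations delegate to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "ttest_from_summary",
    "ttest_two_sample",
    "levene",
    "wilcoxon_ranksum",
    "chi_square_rxc",
    "fisher_exact_2x2",
    "spearman",
    "compare_groups",
    "format_p",
]


@dataclass
class StatResult:
    """Outcome of a single statistical comparison."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    estimate: float | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df <= 0:
            raise ValueError("df must be positive when present")

    @property
    def significant(self) -> bool:
        """True when p < .05, the conventional threshold."""
        return self.p_value < 0.05

    def __str__(self) -> str:
        df = f", df={self.df:g}" if self.df is not None else ""
        return f"{self.method}: stat={self.statistic:.4g}{df}, p={format_p(self.p_value)}"


def format_p(p: float) -> str:
    """Render a p-value in the '.003' report style (3 decimals, no leading 0)."""
    if p < 0.0005:
        return ".000"
    return f"{p:.3f}".lstrip("0")


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def ttest_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> StatResult:
    """Two-sample t-test from group summaries (mean, SD, n).

    ``variant='pooled'`` assumes equal variances (df = n1+n2-2);
    ``variant='welch'`` uses the Satterthwaite approximation. The effect
    estimate is the mean difference (group 2 minus group 1).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        p = 1.0 if mean1 == mean2 else 0.0
        return StatResult(
            method=f"t-test ({variant})", statistic=0.0 if mean1 == mean2 else np.inf,
            p_value=p, df=float(n1 + n2 - 2), estimate=mean2 - mean1,
            notes={"degenerate": "zero variance in both groups"},
        )
    res = sps.ttest_ind_from_stats(
        mean2, sd2, n2, mean1, sd1, n1, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatResult(
        method=f"t-test ({variant})",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        estimate=mean2 - mean1,
    )


def ttest_two_sample(x, y, variant: str = "pooled") -> StatResult:
    """Two-sample t-test on raw data; equals the summary-statistic test
    applied to the samples' own mean/SD/n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    return ttest_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size,
        variant=variant,
    )


def levene(x, y, center: str = "mean") -> StatResult:
    """Levene's test for equality of variances (center='mean' is the SPSS
    default; center='median' gives the Brown-Forsythe variant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = sps.levene(x, y, center=center)
    if np.isnan(stat):  # identical samples -> zero spread in deviations
        stat, p = 0.0, 1.0
    return StatResult(
        method=f"levene ({center})", statistic=float(stat), p_value=float(p),
        df=float(x.size + y.size - 2),
        estimate=float(np.var(y, ddof=1) / np.var(x, ddof=1))
        if np.var(x, ddof=1) > 0 else None,
    )


# ---------------------------------------------------------------------------
# rank and contingency tests
# ---------------------------------------------------------------------------

def wilcoxon_ranksum(x, y) -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact p for combined n <= 20 without ties, normal approximation with
    tie correction otherwise. Reports each sample's median and IQR in the
    notes, the convention for non-normal variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)

    def iqr(v):
        q1, q3 = np.percentile(v, [25, 75])
        return float(np.median(v)), float(q3 - q1)

    mx, ix = iqr(x)
    my, iy = iqr(y)
    return StatResult(
        method=f"wilcoxon rank-sum ({method})",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        estimate=my - mx,
        notes={"median_iqr_x": (mx, ix), "median_iqr_y": (my, iy)},
    )


def chi_square_rxc(table) -> StatResult:
    """Pearson chi-square test on an r x c contingency table.

    No continuity correction is applied. The minimum expected cell count
    is reported in the notes (the usual validity caveat for small tables).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult(
        method="chi-square (Pearson, no correction)",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.dof),
        notes={"min_expected": float(res.expected_freq.min())},
    )


def fisher_exact_2x2(table) -> StatResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p sums the hypergeometric probabilities (margins fixed)
    of every table no more probable than the observed one. One-sided p
    and the sample odds ratio are reported in the notes.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return StatResult(
            method="fisher exact", statistic=np.nan, p_value=1.0,
            notes={"degenerate": "zero margin"},
        )
    odds, p_two = sps.fisher_exact(table.astype(int), alternative="two-sided")
    _, p_less = sps.fisher_exact(table.astype(int), alternative="less")
    _, p_greater = sps.fisher_exact(table.astype(int), alternative="greater")
    return StatResult(
        method="fisher exact",
        statistic=float(odds),
        p_value=float(p_two),
        estimate=float(odds),
        notes={"p_one_sided": float(min(p_less, p_greater))},
    )


def spearman(x, y) -> StatResult:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    rho, p = sps.spearmanr(x, y)
    return StatResult(
        method="spearman", statistic=float(rho), p_value=float(p),
        df=float(x.size - 2), estimate=float(rho),
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    grouping: str,
    groups: tuple | None = None,
    alpha: float = 0.05,
) -> StatResult:
    """Compare ``variable`` between two levels of ``grouping``.

    Continuous variables: Shapiro-Wilk normality gate (both groups, at
    ``alpha``) -> pooled t-test (Welch when Levene rejects equal
    variances) or Wilcoxon rank-sum. Categorical/boolean variables:
    Pearson chi-square on the crosstab, with Fisher's exact p attached in
    the notes for 2x2 tables (and a warning when any expected count is
    below 5). The branch taken is always recorded in the notes.
    """
    if groups is None:
        levels = list(pd.unique(cohort[grouping]))
        if len(levels) != 2:
            raise ValueError(
                f"grouping {grouping!r} has {len(levels)} levels; pass groups="
            )
        groups = tuple(levels)
    sub = cohort[cohort[grouping].isin(groups)]
    col = sub[variable]

    if pd.api.types.is_bool_dtype(col) or not pd.api.types.is_numeric_dtype(col):
        tab = pd.crosstab(sub[grouping], col).reindex(index=list(groups))
        table = tab.to_numpy()
        res = chi_square_rxc(table)
        res.notes["branch"] = "chi-square"
        res.notes["table"] = table.tolist()
        if table.shape == (2, 2):
            fisher = fisher_exact_2x2(table)
            res.notes["fisher_p"] = fisher.p_value
            if res.notes["min_expected"] < 5:
                res.notes["warning"] = (
                    "expected count < 5; Fisher's exact p reported alongside"
                )
        return res

    x = col[sub[grouping] == groups[0]].dropna().to_numpy(dtype=float)
    y = col[sub[grouping] == groups[1]].dropna().to_numpy(dtype=float)
    if x.size < 3 or y.size < 3:
        res = wilcoxon_ranksum(x, y)
        res.notes["branch"] = "wilcoxon (group too small for normality gate)"
        return res
    p_norm = min(sps.shapiro(x).pvalue, sps.shapiro(y).pvalue)
    if p_norm < alpha:
        res = wilcoxon_ranksum(x, y)
        res.notes["branch"] = "wilcoxon"
        res.notes["shapiro_min_p"] = float(p_norm)
        return res
    lev = levene(x, y)
    variant = "welch" if lev.p_value < alpha else "pooled"
    res = ttest_two_sample(x, y, variant=variant)
    res.notes["branch"] = f"t-test ({variant})"
    res.notes["shapiro_min_p"] = float(p_norm)
    res.notes["levene_p"] = lev.p_value
    return res
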