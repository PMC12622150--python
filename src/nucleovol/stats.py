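"""Test selection, two-sample comparison, Bonferroni correction and
box-plot summaries.

The comparison protocol is the one common in high-content screening
reports: Shapiro-Wilk normality on each sample; if either sample departs
from normality (p below ``alpha_normality``) the two-sided Mann-Whitney U
test is used, otherwise variance homogeneity is checked with Levene's test
and, if it holds, an unpaired two-tailed t-test; a Levene rejection also
falls back to Mann-Whitney (a Welch t-test is available instead via
``unequal_var="welch"``).  Raw p-values are Bonferroni-adjusted by the
family size ``m`` and mapped to the conventional significance labels
(ns / * / ** / *** / ****, thresholds inclusive).

Mann-Whitney p-values are exact (full null enumeration) whenever the
smaller sample has at most 8 observations and there are no ties, and use
the tie-corrected normal approximation with continuity correction
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "BoxplotStats",
    "choose_test",
    "compare",
    "significance_label",
    "boxplot_summary",
]

EXACT_MWU_MAX_N = 8


@dataclass
class ComparisonResult:
    """Outcome of one two-sample comparison within a family of ``m``."""

    metric: str
    group_names: tuple[str, str]
    n: tuple[int, int]
    test_used: str  # "mann_whitney_u" | "t_test" | "welch_t_test"
    statistic: float
    p_raw: float
    p_adjusted: float
    m: int
    label: str
    percent_change: float


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 3:
        raise ValueError(
            f"sample {name!r} has n={arr.size}; need n >= 3 (Shapiro-Wilk undefined)"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def choose_test(x, y, alpha_normality: float = 0.05) -> str:
    """Select the two-sample test by the normality/variance gate.

    Returns ``"mann_whitney_u"`` if Shapiro-Wilk rejects normality for
    either sample at ``alpha_normality``, or (as a conservative fallback)
    if Levene's test rejects variance homogeneity at 0.05; otherwise
    ``"t_test"``.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    # identical constant samples: Shapiro is undefined; treat as "cannot
    # reject normality" so the downstream test reports p ~ 1
    for s in (x, y):
        if np.ptp(s) > 0 and sps.shapiro(s).pvalue < alpha_normality:
            return "mann_whitney_u"
    if np.ptp(x) > 0 or np.ptp(y) > 0:
        if sps.levene(x, y, center="mean").pvalue < 0.05:
            return "mann_whitney_u"
    return "t_test"


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MWU_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare(
    x,
    y,
    m: int = 1,
    metric: str = "",
    group_names: tuple[str, str] = ("control", "treated"),
    test: str | None = None,
    alpha_normality: float = 0.05,
    unequal_var: str = "mann_whitney_u",
) -> ComparisonResult:
    """Two-sided two-sample comparison with Bonferroni adjustment by ``m``.

    ``x`` is the control group for the percent-change convention
    ``100 * (mean_y - mean_x) / mean_x``.  ``test`` forces
    ``"mann_whitney_u"`` or ``"t_test"``, bypassing the gate;
    ``unequal_var`` chooses the Levene fallback (``"welch"`` for a Welch
    t-test instead of Mann-Whitney).
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    used = test or choose_test(x, y, alpha_normality=alpha_normality)
    if used == "mann_whitney_u" and test is None and unequal_var == "welch":
        # re-derive: only swap to Welch when the gate tripped on variance
        shapiro_ok = all(
            np.ptp(s) == 0 or sps.shapiro(s).pvalue >= alpha_normality for s in (x, y)
        )
        if shapiro_ok:
            used = "welch_t_test"
    if used == "mann_whitney_u":
        stat, p = _mwu(x, y)
    elif used == "t_test":
        res = sps.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif used == "welch_t_test":
        res = sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {used!r}")
    if np.isnan(p):  # identical constant samples
        p = 1.0
    p_adj = min(1.0, p * m)
    return ComparisonResult(
        metric=metric,
        group_names=group_names,
        n=(x.size, y.size),
        test_used=used,
        statistic=stat,
        p_raw=p,
        p_adjusted=p_adj,
        m=m,
        label=significance_label(p_adj),
        percent_change=float(100.0 * (y.mean() - x.mean()) / x.mean()),
    )


def significance_label(p_adjusted: float) -> str:
    """Map an adjusted p-value to the printed convention:
    ns: p > 0.05; *: p <= 0.05; **: p <= 0.01; ***: p <= 0.001;
    ****: p <= 0.0001 (boundaries inclusive)."""
    p = float(p_adjusted)
    if not (0.0 <= p <= 1.0) or np.isnan(p):
        raise ValueError(f"p-value must be in [0, 1], got {p_adjusted}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class BoxplotStats:
    """Five-number summary with Tukey 1.5 x IQR whiskers.

    Quartiles use linear interpolation (the numpy default).  Whiskers
    extend to the most extreme data point inside the 1.5 x IQR fences;
    points beyond are listed as outliers.
    """

    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def boxplot_summary(samples: dict[str, np.ndarray]) -> dict[str, BoxplotStats]:
    """Per-group box-plot statistics for plotting-independent reporting."""
    out: dict[str, BoxplotStats] = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        out[name] = BoxplotStats(
            n=arr.size,
            minimum=float(arr.min()),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            maximum=float(arr.max()),
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
            outliers=sorted(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)]),
        )
    return out
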