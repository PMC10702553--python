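"""Reliability and comparison statistics for paired morphometric measurements.

The battery consists of:

* **ICC(3,1)** — two-way mixed-effects, single-rating, consistency
  intraclass correlation, computed from the two-way ANOVA mean squares
  ``(MS_rows - MS_error) / (MS_rows + (k - 1) MS_error)`` with the
  F-distribution confidence interval.  Qualitative bands follow the usual
  guideline cut-offs: below 0.50 poor, 0.50-0.75 fair, 0.75-0.90 good,
  0.90 and above excellent (both cut-offs closed on the right).
* **Bland--Altman** — bias and 95% limits of agreement of paired
  differences, with proportional bias assessed by regressing the
  differences on the pair means.
* **Shapiro--Wilk gated paired comparison** — Wilcoxon signed-rank when
  normality of the differences is rejected at 5%, paired t otherwise.
* **One-way ANOVA** — fixed effects, for comparing parallel sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05

BAND_POOR = "poor"
BAND_FAIR = "fair"
BAND_GOOD = "good"
BAND_EXCELLENT = "excellent"


def icc_band(icc: float) -> str:
    """Qualitative reliability band for an ICC estimate."""
    if icc < 0.50:
        return BAND_POOR
    if icc < 0.75:
        return BAND_FAIR
    if icc < 0.90:
        return BAND_GOOD
    return BAND_EXCELLENT


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    f_stat: float
    p_value: float
    band: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.icc > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa: tuple[float, float]
    sd_diff: float
    proportional_bias_slope: float
    proportional_bias_p: float

    def __post_init__(self) -> None:
        lo, hi = self.loa
        if abs(lo - (self.bias - 1.96 * self.sd_diff)) > 1e-9 or abs(
            hi - (self.bias + 1.96 * self.sd_diff)
        ) > 1e-9:
            raise ValueError("limits of agreement must equal bias +/- 1.96 * sd_diff")


@dataclass(frozen=True)
class PairedComparison:
    test_used: str  # "wilcoxon" or "paired_t"
    statistic: float
    p_value: float
    normality_p: float
    wilcoxon_p: float
    t_p: float
    degenerate: bool = False


def icc_single_rating(ratings: np.ndarray, alpha: float = ALPHA) -> ICCResult:
    """ICC(3,1): two-way mixed effects, single rating, consistency.

    ``ratings`` is an ``n_subjects x k_raters`` table with no missing
    cells.  The estimate comes from the two-way ANOVA decomposition
    (subjects x raters, no replication); the confidence interval uses the
    exact F method with ``F = MS_rows / MS_error`` on
    ``(n - 1, (n - 1)(k - 1))`` degrees of freedom.  Zero between-subject
    and residual variance (all agreement, no spread) is flagged degenerate.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D table (subjects x raters)")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain missing or non-finite cells; no imputation")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ms_rows <= 0 and ms_err <= 0:
        return ICCResult(
            icc=float("nan"), ci95=(float("nan"), float("nan")),
            f_stat=float("nan"), p_value=float("nan"), band=BAND_POOR, degenerate=True,
        )
    if ms_err == 0:  # perfect consistency
        return ICCResult(icc=1.0, ci95=(1.0, 1.0), f_stat=float("inf"), p_value=0.0,
                         band=BAND_EXCELLENT)

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_rows / ms_err
    p = float(sps.f.sf(f_obs, df1, df2))
    f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))
    return ICCResult(icc=float(icc), ci95=(float(ci[0]), float(ci[1])),
                     f_stat=float(f_obs), p_value=p, band=icc_band(float(icc)))


def bland_altman(
    method_a: np.ndarray, method_b: np.ndarray, alpha: float = ALPHA
) -> BlandAltmanResult:
    """Agreement between two measurement methods on paired values.

    Bias is the mean of ``a - b``; the limits of agreement are
    ``bias +/- 1.96 sd`` of the differences.  Proportional bias is the
    slope of the regression of the differences on the pair means, with its
    p-value reported at the given significance level's two-sided test.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("method_a and method_b must be 1-D arrays of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (a + b) / 2.0
    if np.ptp(means) == 0 or sd == 0:
        slope, slope_p = 0.0, 1.0
    else:
        fit = sps.linregress(means, d)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(
        bias=bias,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        sd_diff=sd,
        proportional_bias_slope=slope,
        proportional_bias_p=slope_p,
    )


def paired_compare(x: np.ndarray, y: np.ndarray, alpha: float = ALPHA) -> PairedComparison:
    """Shapiro--Wilk gated paired comparison.

    Differences are tested for normality with Shapiro--Wilk; if normality
    is rejected at ``alpha`` the Wilcoxon signed-rank test is used
    (two-sided; zero differences dropped; exact null distribution when the
    effective n is at most 25 and there are no ties, normal approximation
    with tie and continuity correction otherwise), else the paired t test.
    Both p-values are reported alongside the gate decision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 6:
        raise ValueError("need at least 6 pairs")
    d = x - y
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return PairedComparison(
            test_used="wilcoxon", statistic=float("nan"), p_value=1.0,
            normality_p=float("nan"), wilcoxon_p=1.0, t_p=1.0, degenerate=True,
        )
    if np.ptp(d) == 0:  # constant nonzero shift: Shapiro undefined, clearly non-normal gate
        shapiro_p = 0.0
    else:
        shapiro_p = float(sps.shapiro(d).pvalue)

    method = "exact" if (nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size) else "approx"
    w = sps.wilcoxon(x, y, zero_method="wilcox", correction=(method == "approx"),
                     alternative="two-sided", method=method)
    t = sps.ttest_rel(x, y)
    use_wilcoxon = shapiro_p < alpha
    return PairedComparison(
        test_used="wilcoxon" if use_wilcoxon else "paired_t",
        statistic=float(w.statistic) if use_wilcoxon else float(t.statistic),
        p_value=float(w.pvalue) if use_wilcoxon else float(t.pvalue),
        normality_p=shapiro_p,
        wilcoxon_p=float(w.pvalue),
        t_p=float(t.pvalue),
    )


def parallel_sections_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across parallel sections; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.ndim != 1 or g.size < 2:
            raise ValueError("each group needs at least 2 values")
    if all(np.ptp(g) == 0 for g in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0  # no variance anywhere: nothing to compare
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)
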