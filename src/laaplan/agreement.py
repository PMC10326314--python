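"""Method-comparison statistics for paired diameter measurements.

Implements the agreement toolbox used to compare sizing modalities
(tomographic vs. fluoroscopic vs. echocardiographic): Bland-Altman bias
and limits of agreement, Pearson correlation with the Taylor qualitative
scale, a normality-driven choice between the paired t-test and the
Wilcoxon signed-rank test, and the single-rating absolute-agreement
two-way random-effects intraclass correlation ICC(2,1) with its
McGraw-Wong F-based confidence interval.  Elementary test statistics
come from scipy.stats; the selection logic, the Bland-Altman quantities
and the ICC ANOVA decomposition are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "RatingsMatrix",
    "AgreementResult",
    "bland_altman",
    "paired_compare",
    "pearson",
    "icc_2_1",
    "report_table",
    "bland_altman_plot",
    "scatter_plot",
]

# Taylor's qualitative scale for |r|
PEARSON_LABELS = ((0.35, "weak"), (0.67, "moderate"), (0.9, "strong"), (1.01, "very strong"))
# Koo & Li's qualitative scale for ICC
ICC_LABELS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (1.01, "excellent"))


@dataclass
class PairedMeasurements:
    """Paired values of one quantity from two methods, by case."""

    case_ids: list
    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if len(self.values_a) != len(self.values_b) or len(self.case_ids) != len(self.values_a):
            raise ValueError("case ids and both value series must have equal length")
        if len(self.values_a) < 3:
            raise ValueError("need at least 3 paired measurements")
        if np.isnan(self.values_a).any() or np.isnan(self.values_b).any():
            raise ValueError("missing values are not allowed in paired data")

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    def __len__(self) -> int:
        return len(self.values_a)


@dataclass
class RatingsMatrix:
    """n subjects x k raters of one quantity (complete, mm)."""

    values: np.ndarray
    subject_ids: list | None = None
    rater_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2D subjects x raters matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if np.isnan(self.values).any():
            raise ValueError("ratings matrix must be complete (no missing cells)")


@dataclass
class AgreementResult:
    """Bland-Altman + correlation + paired-test summary for one comparison."""

    n: int
    bias_mm: float
    sd_mm: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    pearson_r: float = math.nan
    r_pvalue: float = math.nan
    r_label: str = ""
    paired_test_name: str = ""
    paired_pvalue: float = math.nan
    shapiro_pvalue: float = math.nan
    levene_pvalue: float = math.nan
    comparison: str = ""
    extras: dict = field(default_factory=dict)


def bland_altman(
    pm: PairedMeasurements, loa_k: float = 1.96, ci_level: float = 0.95
) -> AgreementResult:
    """Bland-Altman analysis of paired differences a_i - b_i.

    bias = mean difference; sd = sample standard deviation (n-1);
    limits of agreement = bias +- loa_k * sd; the confidence interval of
    the bias uses the t distribution with n-1 degrees of freedom.
    A zero-variance difference series is reported with a warning since
    its limits of agreement are degenerate.
    """
    d = pm.differences
    n = len(d)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        warnings.warn("all paired differences identical; limits of agreement degenerate")
    half = float(stats.t.ppf((1.0 + ci_level) / 2.0, n - 1)) * sd / math.sqrt(n)
    return AgreementResult(
        n=n,
        bias_mm=bias,
        sd_mm=sd,
        loa_low=bias - loa_k * sd,
        loa_high=bias + loa_k * sd,
        bias_ci=(bias - half, bias + half),
        comparison=f"{pm.label_a} vs. {pm.label_b}",
    )


def paired_compare(pm: PairedMeasurements, alpha: float = 0.05) -> tuple[str, float, dict]:
    """Choose and run the adequate paired significance test.

    Shapiro-Wilk on the differences decides: normality not rejected
    (p >= alpha) -> two-sided paired t-test; rejected -> two-sided
    Wilcoxon signed-rank with zero differences dropped and the exact
    null distribution for n <= 25 (small-sample studies demand it).
    Levene's test for equal variances of the two series is computed and
    reported alongside but does not drive the choice.
    """
    d = pm.differences
    levene_stat, levene_p = stats.levene(pm.values_a, pm.values_b)
    diag = {"levene_stat": float(levene_stat), "levene_pvalue": float(levene_p)}
    if np.allclose(d, d[0]):
        # constant differences: Shapiro is undefined; t-test convention
        diag["shapiro_pvalue"] = math.nan
        if np.all(d == 0):
            diag["degenerate"] = "all differences zero"
            return "paired t-test", 1.0, diag
        _, p = stats.ttest_rel(pm.values_a, pm.values_b)
        return "paired t-test", float(p), diag
    sw_stat, sw_p = stats.shapiro(d)
    diag["shapiro_pvalue"] = float(sw_p)
    if sw_p >= alpha:
        _, p = stats.ttest_rel(pm.values_a, pm.values_b)
        return "paired t-test", float(p), diag
    nz = d[d != 0]
    if len(nz) == 0:
        diag["degenerate"] = "all differences zero"
        return "Wilcoxon signed-rank", 1.0, diag
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                         method=method)
    return "Wilcoxon signed-rank", float(res.pvalue), diag


def pearson(pm: PairedMeasurements) -> tuple[float, float, str]:
    """Pearson r with two-sided p-value and Taylor qualitative label."""
    if np.std(pm.values_a) == 0 or np.std(pm.values_b) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance series")
    r, p = stats.pearsonr(pm.values_a, pm.values_b)
    label = next(lab for thr, lab in PEARSON_LABELS if abs(r) < thr or thr > 1.0)
    return float(r), float(p), label


def analyze(pm: PairedMeasurements, loa_k: float = 1.96, ci_level: float = 0.95,
            alpha: float = 0.05) -> AgreementResult:
    """Full agreement analysis: Bland-Altman + Pearson + paired test."""
    res = bland_altman(pm, loa_k=loa_k, ci_level=ci_level)
    test_name, test_p, diag = paired_compare(pm, alpha=alpha)
    res.paired_test_name, res.paired_pvalue = test_name, test_p
    res.shapiro_pvalue = diag.get("shapiro_pvalue", math.nan)
    res.levene_pvalue = diag.get("levene_pvalue", math.nan)
    try:
        res.pearson_r, res.r_pvalue, res.r_label = pearson(pm)
    except ValueError:
        pass  # zero-variance series: correlation left undefined
    return res


# --- intraclass correlation ------------------------------------------------

def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, columns=raters)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2_1(rm: RatingsMatrix, ci_level: float = 0.95) -> tuple[float, float, float, str]:
    """ICC(2,1): single-rating, absolute-agreement, two-way random effects.

    From the two-way ANOVA mean squares (subjects MSR, raters MSC,
    error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval is the McGraw-Wong F-based interval for this
    model.  Returns (icc, ci_low, ci_high, qualitative label by the
    Koo & Li thresholds).  Values <= 0 (no subject variance) are
    reported as computed.
    """
    x = rm.values
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else math.nan

    alpha = 1.0 - ci_level
    if mse == 0 and msc == msr:
        lo, hi = icc, icc  # perfect agreement: interval collapses
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        if math.isinf(a) or math.isinf(b):
            lo, hi = 1.0, 1.0
        else:
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
            f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
    label = next(lab for thr, lab in ICC_LABELS if icc < thr or thr > 1.0)
    return float(icc), float(lo), float(hi), label


# --- reporting -------------------------------------------------------------

def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "n/a"
    return "<0.05" if p < 0.05 else f"{p:.2f}"


def report_table(results: list[AgreementResult]) -> pd.DataFrame:
    """Render comparisons as the standard agreement report table.

    One row per comparison, columns 'Mean deviation ± standard deviation
    in mm; p-value' and 'Pearson correlation coefficient; p-value';
    deviations to one decimal (mm), correlations to two; p-values below
    0.05 printed as '<0.05'.
    """
    if not results:
        raise ValueError("no comparisons to report")
    rows = []
    for r in results:
        rows.append(
            {
                "Comparison": r.comparison,
                "Mean deviation ± standard deviation in mm; p-value":
                    f"{r.bias_mm:.1f} ± {r.sd_mm:.1f}; {_fmt_p(r.paired_pvalue)}",
                "Pearson correlation coefficient; p-value":
                    f"{r.pearson_r:.2f}; {_fmt_p(r.r_pvalue)}",
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot(pm: PairedMeasurements, result: AgreementResult | None = None,
                      ax=None):
    """Bland-Altman plot: zero line, bias line, limits, bias-CI band."""
    import matplotlib.pyplot as plt

    if result is None:
        result = bland_altman(pm)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean_vals = (pm.values_a + pm.values_b) / 2.0
    ax.scatter(mean_vals, pm.differences, color="k", s=18, zorder=3)
    ax.axhline(0.0, color="green", linestyle="--", lw=1)
    ax.axhline(result.bias_mm, color="orange", lw=1.5)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="orange", linestyle="--", lw=1)
    ax.axhspan(*result.bias_ci, color="orange", alpha=0.25, lw=0)
    ax.set_xlabel(f"mean of {pm.label_a} and {pm.label_b} (mm)")
    ax.set_ylabel(f"{pm.label_a} − {pm.label_b} (mm)")
    return ax


def scatter_plot(pm: PairedMeasurements, ax=None):
    """Scatter of method B vs. A with identity and least-squares lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pm.values_a, pm.values_b, color="k", s=18, zorder=3)
    lims = [min(pm.values_a.min(), pm.values_b.min()),
            max(pm.values_a.max(), pm.values_b.max())]
    ax.plot(lims, lims, "g--", lw=1)
    slope, intercept = np.polyfit(pm.values_a, pm.values_b, 1)
    xs = np.asarray(lims)
    ax.plot(xs, slope * xs + intercept, color="orange", lw=1.5)
    ax.set_xlabel(f"{pm.label_a} (mm)")
    ax.set_ylabel(f"{pm.label_b} (mm)")
    return ax
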