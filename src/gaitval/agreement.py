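"""Method-comparison statistics for paired per-cycle gait variables.

Given the same cycles measured by two trackers, agreement is quantified
with the battery standard in method-comparison studies:

* a QQ normality triage (probability-plot points and a linearity score);
* for normally distributed variables, the two-way, absolute-agreement,
  single-measure intraclass correlation coefficient ICC(A,1)
  (McGraw & Wong), with its F-based 95% confidence interval;
* otherwise Lin's concordance correlation coefficient (CCC), which
  penalises both imprecision and location/scale shift, with the Fisher-z
  asymptotic interval;
* Pearson's correlation coefficient (CC) for the linear relationship;
* Bland-Altman limits of agreement (mean difference +/- 1.96 SD);
* graded interpretation scales for each coefficient.

The ICC scale (Koo & Li): < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good,
>= 0.9 excellent.  The CCC scale (McBride): < 0.90 poor, 0.90-0.95
moderate, 0.95-0.99 substantial, >= 0.99 almost perfect.  The CC scale
(Schober): < 0.10 negligible, then weak / moderate / strong, >= 0.90 very
strong.  Lower bounds are inclusive and the top class is closed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDistributionError, UndefinedStatisticError

CI_LEVEL = 0.95


@dataclass(frozen=True)
class PairedSeries:
    """Cycle-aligned values of one variable from two methods."""

    variable: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D and of equal length")
        if len(x) < 3:
            raise ValueError(f"need n >= 3 pairs, got {len(x)}")

    @property
    def n(self) -> int:
        return len(self.x)

    def swapped(self) -> "PairedSeries":
        return PairedSeries(self.variable, self.y, self.x)


@dataclass(frozen=True)
class QQResult:
    """Probability-plot data: sorted sample vs fitted normal quantiles."""

    sample: np.ndarray
    theoretical: np.ndarray
    mu: float
    sigma: float
    linearity: float
    #: the y = x reference line drawn through the plot
    reference_slope: float = 1.0
    reference_intercept: float = 0.0


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    lower_loa: float
    upper_loa: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class AgreementResult:
    """Full comparison of one variable between two methods."""

    variable: str
    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    normality: str                 # "normal" | "non-normal"
    stat_type: str                 # "ICC" | "CCC"
    stat: float
    ci_low: float
    ci_high: float
    pearson: float
    icc_category: str | None
    ccc_category: str | None
    cc_category: str
    bland_altman: BlandAltman


# ---------------------------------------------------------------------------
# normality triage
# ---------------------------------------------------------------------------

def qq_points(values: np.ndarray) -> QQResult:
    """Normal probability-plot points for a sample.

    The sorted sample values (abscissa) are paired with the normal
    quantiles ``mu + sigma * Phi^-1((i - 0.5)/n)`` (ordinate), where mu
    and sigma come from the least-squares probability-plot fit of the
    sample on the standard normal quantiles.  ``linearity`` is the
    correlation of the point cloud (the probability-plot correlation
    coefficient); values near 1 indicate compatibility with a Gaussian.
    """
    v = np.sort(np.asarray(values, float))
    n = len(v)
    if n < 3:
        raise ValueError(f"need n >= 3 values, got {n}")
    if np.ptp(v) == 0:
        raise DegenerateDistributionError("zero-variance sample")
    p = (np.arange(1, n + 1) - 0.5) / n
    q = stats.norm.ppf(p)
    sigma, mu = np.polyfit(q, v, 1)
    theo = mu + sigma * q
    linearity = float(np.corrcoef(v, q)[0, 1])
    return QQResult(sample=v, theoretical=theo, mu=float(mu),
                    sigma=float(sigma), linearity=linearity)


def suggest_normality(values: np.ndarray, linearity_threshold: float = 0.995) -> bool:
    """Automated stand-in for visual QQ inspection.

    True when the probability-plot correlation reaches the threshold.
    Advisory only: the pipeline takes per-variable verdicts as explicit
    input and logs when this suggestion is used instead.
    """
    return qq_points(values).linearity >= linearity_threshold


# ---------------------------------------------------------------------------
# agreement coefficients
# ---------------------------------------------------------------------------

def _anova_two_way(x: np.ndarray, y: np.ndarray):
    """Mean squares of the subjects-by-methods two-way layout (k = 2)."""
    m = np.column_stack([x, y])
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_a1(pairs: PairedSeries, ci_level: float = CI_LEVEL):
    """ICC(A,1): two-way, absolute agreement, single measure.

    Subjects are cycles, raters are the two methods.  Estimate
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` from the
    two-way ANOVA decomposition, confidence interval by the McGraw-Wong
    F-based formula.  Returns ``(estimate, (low, high))``.
    """
    msr, msc, mse, n, k = _anova_two_way(pairs.x, pairs.y)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise UndefinedStatisticError(
            "zero subject variance: ICC undefined for constant data"
        )
    icc = (msr - mse) / denom
    alpha = 1 - ci_level
    if mse == 0 and msc == 0:
        return float(icc), (float(icc), float(icc))
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else n - 1
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (n * (msr - f_upper * mse)
          / (f_upper * (k * msc + (k * n - k - n) * mse) + n * msr))
    hi = (n * (f_lower * msr - mse)
          / (k * msc + (k * n - k - n) * mse + n * f_lower * msr))
    return float(icc), (float(lo), float(hi))


def lin_ccc(pairs: PairedSeries, ci_level: float = CI_LEVEL):
    """Lin's concordance correlation coefficient with Fisher-z interval.

    Moments use the 1/n convention (Lin 1989):
    ``CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)``.
    Returns ``(estimate, (low, high))``.
    """
    x, y, n = pairs.x, pairs.y, pairs.n
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise UndefinedStatisticError("both series constant and equal: CCC undefined")
    ccc = 2 * sxy / denom
    # Fisher-z asymptotic interval (Lin 1989, corrected 2000)
    if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1:
        return float(ccc), (float(ccc), float(ccc))
    r = sxy / np.sqrt(sx2 * sy2)
    if r == 0:
        return float(ccc), (float("nan"), float("nan"))
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2 = ccc**2
    var_z = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 4 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - 2 * ccc**4 * u**4 / (r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    z = np.arctanh(ccc)
    zcrit = stats.norm.ppf(1 - (1 - ci_level) / 2)
    half = zcrit * np.sqrt(max(var_z, 0.0))
    return float(ccc), (float(np.tanh(z - half)), float(np.tanh(z + half)))


def ccc_from_summary(
    mean_x: float, sd_x: float, mean_y: float, sd_y: float, r: float,
) -> float:
    """Lin's CCC reconstructed from per-method summary statistics.

    ``CCC = 2 r s_x s_y / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)``.
    Useful when only published means, SDs and the Pearson correlation are
    available; the SD convention cancels as long as both methods use the
    same one.
    """
    denom = sd_x**2 + sd_y**2 + (mean_x - mean_y) ** 2
    if denom == 0:
        raise UndefinedStatisticError("degenerate summary statistics")
    return float(2 * r * sd_x * sd_y / denom)


def pearson_cc(pairs: PairedSeries) -> float:
    """Product-moment correlation in [-1, 1]."""
    x, y = pairs.x, pairs.y
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def bland_altman(pairs: PairedSeries) -> BlandAltman:
    """Limits-of-agreement summary with per-point (mean, difference) data.

    Differences are reference-minus-test (x - y); limits are
    ``mean_diff +/- 1.96 * SD`` with the sample (n-1) SD.
    """
    x, y = pairs.x, pairs.y
    diffs = x - y
    means = (x + y) / 2
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        lower_loa=mean_diff - 1.96 * sd_diff,
        upper_loa=mean_diff + 1.96 * sd_diff,
        means=means,
        diffs=diffs,
    )


# ---------------------------------------------------------------------------
# interpretation scales
# ---------------------------------------------------------------------------

_SCALES = {
    "icc": ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (None, "excellent")),
    "ccc": ((0.90, "poor"), (0.95, "moderate"), (0.99, "substantial"),
            (None, "almost perfect")),
    "cc": ((0.10, "negligible"), (0.40, "weak"), (0.70, "moderate"),
           (0.90, "strong"), (None, "very strong")),
}


def classify(statistic: str, value: float) -> str:
    """Graded label for an agreement/correlation coefficient.

    ``statistic`` is one of ``icc``, ``ccc``, ``cc``.  Class lower bounds
    are inclusive, upper bounds exclusive, and the top class is closed at
    1.  The CC scale grades the strength of association, so the magnitude
    is classified.
    """
    kind = statistic.lower()
    if kind not in _SCALES:
        raise ValueError(f"unknown statistic kind {statistic!r}")
    if not -1 <= value <= 1:
        raise ValueError(f"coefficient {value} outside [-1, 1]")
    v = abs(value) if kind == "cc" else value
    for bound, label in _SCALES[kind]:
        if bound is None or v < bound:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# per-variable summary
# ---------------------------------------------------------------------------

def summarize_variable(pairs: PairedSeries, normal: bool) -> AgreementResult:
    """Full agreement summary for one variable.

    The normality verdict selects the agreement coefficient: ICC(A,1)
    for normal variables, Lin's CCC otherwise.  Pearson's CC and
    Bland-Altman limits are reported either way.
    """
    if normal:
        stat, (lo, hi) = icc_a1(pairs)
        stat_type = "ICC"
        icc_cat, ccc_cat = classify("icc", stat), None
    else:
        stat, (lo, hi) = lin_ccc(pairs)
        stat_type = "CCC"
        icc_cat, ccc_cat = None, classify("ccc", stat)
    cc = pearson_cc(pairs)
    return AgreementResult(
        variable=pairs.variable,
        n=pairs.n,
        mean_x=float(pairs.x.mean()),
        sd_x=float(pairs.x.std(ddof=1)),
        mean_y=float(pairs.y.mean()),
        sd_y=float(pairs.y.std(ddof=1)),
        normality="normal" if normal else "non-normal",
        stat_type=stat_type,
        stat=stat,
        ci_low=lo,
        ci_high=hi,
        pearson=cc,
        icc_category=icc_cat,
        ccc_category=ccc_cat,
        cc_category=classify("cc", cc),
        bland_altman=bland_altman(pairs),
    )


REPORT_COLUMNS = (
    "variable", "n", "mean_x", "sd_x", "mean_y", "sd_y", "normality",
    "stat_type", "stat", "ci_low", "ci_high", "cc", "icc_category",
    "ccc_category", "cc_category", "ba_mean_diff", "ba_sd_diff",
    "ba_lower_loa", "ba_upper_loa",
)


def results_to_frame(results: list[AgreementResult]) -> pd.DataFrame:
    """One report row per variable with the documented column set."""
    rows = []
    for r in results:
        rows.append({
            "variable": r.variable, "n": r.n,
            "mean_x": r.mean_x, "sd_x": r.sd_x,
            "mean_y": r.mean_y, "sd_y": r.sd_y,
            "normality": r.normality, "stat_type": r.stat_type,
            "stat": r.stat, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "cc": r.pearson,
            "icc_category": r.icc_category, "ccc_category": r.ccc_category,
            "cc_category": r.cc_category,
            "ba_mean_diff": r.bland_altman.mean_diff,
            "ba_sd_diff": r.bland_altman.sd_diff,
            "ba_lower_loa": r.bland_altman.lower_loa,
            "ba_upper_loa": r.bland_altman.upper_loa,
        })
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
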