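"""Test-retest reliability and method-agreement statistics.

Implements the normal-theory reliability chain used throughout
musculoskeletal morphometry:

* **ICC(3,1)** — two-way mixed-effects (random subjects, fixed raters),
  consistency, single-measure intraclass correlation, computed from the
  two-way ANOVA mean squares::

      ICC = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

  with the Shrout–Fleiss F-based 95% confidence interval.
* **SEm** — standard error of measurement, ``SD * sqrt(1 - ICC)``.
* **MDD** (MDC95) — minimal detectable difference, ``SEm * 1.96 * sqrt(2)``,
  also expressed relative to the group mean as a percentage.
* **Bland–Altman** — mean difference (bias) and 95% limits of agreement
  ``bias ± 1.96 * SD(diff)``, with the LoA half-width expressed as a
  percentage of the pooled mean of the two compared methods.

1.96 is used as a fixed normal quantile throughout (not a t quantile),
matching the conventional SEm/MDD definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "RepeatedMeasures",
    "ICCResult",
    "ReliabilityRow",
    "MethodComparison",
    "IntraclassCorrelation",
    "ReliabilityAnalysis",
    "BlandAltman",
    "icc_3_1",
    "sem",
    "sem_ci",
    "mdd",
    "relative_mdd",
    "pearson_r",
    "bland_altman",
    "loa_percent",
    "welch_t",
]

Z95 = 1.96
SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class RepeatedMeasures:
    """An n-units x k-trials complete-case measurement matrix."""

    matrix: np.ndarray
    units: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        _validate_matrix(m)


def _validate_matrix(m: np.ndarray) -> None:
    if m.ndim != 2:
        raise ValueError("repeated-measures data must be a 2-D (units x trials) matrix")
    n, k = m.shape
    if n < 3:
        raise ValueError(f"need at least 3 units for reliability analysis, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 trials, got {k}")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing or non-finite cells are not supported (complete-case only)")


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, RepeatedMeasures):
        return data.matrix
    m = np.asarray(data, dtype=float)
    _validate_matrix(m)
    return m


@dataclass(frozen=True)
class ICCResult:
    """ICC point estimate with its 95% confidence bounds."""

    estimate: float
    ci_low: float
    ci_high: float
    model: str = "3,1"


@dataclass(frozen=True)
class ReliabilityRow:
    """One reliability-table row: ICC, SEm, MDD and relative MDD%."""

    icc: ICCResult
    mean: float
    sd: float
    sem: float
    sem_ci: tuple
    mdd: float
    mdd_pct: float
    n_units: int = 0


@dataclass(frozen=True)
class MethodComparison:
    """Pearson correlation plus Bland–Altman agreement for one method pair.

    ``bias`` is first-method minus second-method; ``loa_pct`` is the LoA
    half-width (1.96*SD of differences) as a percent of ``reference_mean``,
    the average of the two methods' group means.
    """

    r: float
    bias: float
    loa_low: float
    loa_high: float
    loa_pct: float
    reference_mean: float
    sd_diff: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


class IntraclassCorrelation(BaseEstimator):
    """ICC(3,1): two-way mixed, consistency, single measure.

    Parameters
    ----------
    confidence : float
        Confidence level for the Shrout–Fleiss F-based interval (default 0.95).

    Attributes (after ``fit`` on an n x k matrix)
    ----------
    estimate_ : float
        ICC point estimate, in [-1/(k-1), 1].
    ci_low_, ci_high_ : float
        Confidence bounds.
    ms_rows_, ms_cols_, ms_error_ : float
        Two-way ANOVA mean squares (rows = units, cols = trials).
    n_, k_ : int
    """

    def __init__(self, confidence: float = 0.95):
        self.confidence = confidence

    def fit(self, X, y=None) -> "IntraclassCorrelation":
        m = _as_matrix(X)
        n, k = m.shape
        grand = m.mean()
        row_means = m.mean(axis=1)
        col_means = m.mean(axis=0)
        ss_total = np.sum((m - grand) ** 2)
        ss_rows = k * np.sum((row_means - grand) ** 2)
        ss_cols = n * np.sum((col_means - grand) ** 2)
        ss_err = ss_total - ss_rows - ss_cols
        df_rows, df_cols = n - 1, k - 1
        df_err = df_rows * df_cols
        msr = ss_rows / df_rows
        msc = ss_cols / df_cols
        mse = ss_err / df_err
        if msr + (k - 1) * mse <= 0:
            raise ValueError("zero total variance: ICC is undefined")
        # mathematically bounded by 1; guard the float round-off overshoot
        icc = min((msr - mse) / (msr + (k - 1) * mse), 1.0)

        # Shrout-Fleiss interval: invert the F statistic MSR/MSE
        alpha = 1.0 - self.confidence
        if mse == 0.0:
            lo = hi = 1.0
        else:
            f_obs = msr / mse
            f_crit_lo = stats.f.ppf(1 - alpha / 2, df_rows, df_err)
            f_crit_hi = stats.f.ppf(1 - alpha / 2, df_err, df_rows)
            fl = f_obs / f_crit_lo
            fu = f_obs * f_crit_hi
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        self.estimate_ = float(icc)
        self.ci_low_ = float(min(lo, icc))
        self.ci_high_ = float(max(hi, icc))
        self.ms_rows_ = float(msr)
        self.ms_cols_ = float(msc)
        self.ms_error_ = float(mse)
        self.n_, self.k_ = n, k
        return self

    def result_(self) -> ICCResult:
        return ICCResult(self.estimate_, self.ci_low_, self.ci_high_, model="3,1")


def icc_3_1(data, confidence: float = 0.95) -> ICCResult:
    """ICC(3,1) with Shrout–Fleiss confidence interval (functional form)."""
    return IntraclassCorrelation(confidence=confidence).fit(data).result_()


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement: ``SD * sqrt(1 - ICC)``."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if icc > 1:
        raise ValueError("icc cannot exceed 1")
    return sd * np.sqrt(1.0 - icc)


def sem_ci(mean: float, sem_value: float) -> tuple:
    """95% interval around the group mean: ``mean ± 1.96 * SEm``."""
    if sem_value < 0:
        raise ValueError("sem must be non-negative")
    half = Z95 * sem_value
    return (mean - half, mean + half)


def mdd(sem_value: float) -> float:
    """Minimal detectable difference (MDC95): ``SEm * 1.96 * sqrt(2)``."""
    if sem_value < 0:
        raise ValueError("sem must be non-negative")
    return sem_value * Z95 * SQRT2


def relative_mdd(mdd_value: float, mean: float) -> float:
    """MDD as a percentage of the group mean: ``100 * MDD / mean``."""
    if mean <= 0:
        raise ValueError("group mean must be positive for a relative MDD")
    return 100.0 * mdd_value / mean


def loa_percent(loa_low: float, loa_high: float, reference_mean: float) -> float:
    """LoA half-width as a percent of the reference (pooled methods) mean.

    ``100 * ((loa_high - loa_low) / 2) / reference_mean`` — the scale-free
    agreement summary used to compare method pairs across measurands.
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    if loa_high < loa_low:
        raise ValueError("loa_high must be >= loa_low")
    return 100.0 * 0.5 * (loa_high - loa_low) / reference_mean


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def welch_t(group1, group2) -> tuple:
    """Welch two-sample t test (unequal variances), two-sided.

    Returns ``(statistic, p_value)``.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(g1) == 0 and np.var(g2) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


class ReliabilityAnalysis(BaseEstimator):
    """Full test-retest reliability chain on an n x k measurement matrix.

    Computes ICC(3,1), the measurement SD, SEm, the 95% SEm interval around
    the group mean, MDD and relative MDD%.

    Parameters
    ----------
    sd_mode : {"pooled", "trial_means"}
        ``"pooled"`` (default) takes the sample SD of all n*k individual
        measurements; ``"trial_means"`` takes the SD of per-unit trial means.
    confidence : float
        Confidence level for the ICC interval.
    """

    def __init__(self, sd_mode: str = "pooled", confidence: float = 0.95):
        self.sd_mode = sd_mode
        self.confidence = confidence

    def fit(self, X, y=None) -> "ReliabilityAnalysis":
        if self.sd_mode not in ("pooled", "trial_means"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        m = _as_matrix(X)
        icc_est = IntraclassCorrelation(confidence=self.confidence).fit(m)
        self.icc_ = icc_est.result_()
        self.mean_ = float(m.mean())
        if self.sd_mode == "pooled":
            self.sd_ = float(np.std(m.ravel(), ddof=1))
        else:
            self.sd_ = float(np.std(m.mean(axis=1), ddof=1))
        self.sem_ = sem(self.sd_, self.icc_.estimate)
        self.sem_ci_ = sem_ci(self.mean_, self.sem_)
        self.mdd_ = mdd(self.sem_)
        self.mdd_pct_ = relative_mdd(self.mdd_, self.mean_)
        self.n_, self.k_ = m.shape
        return self

    def row_(self) -> ReliabilityRow:
        return ReliabilityRow(
            icc=self.icc_,
            mean=self.mean_,
            sd=self.sd_,
            sem=self.sem_,
            sem_ci=self.sem_ci_,
            mdd=self.mdd_,
            mdd_pct=self.mdd_pct_,
            n_units=self.n_,
        )


class BlandAltman(BaseEstimator):
    """Bland–Altman agreement between two paired measurement methods.

    ``fit(a, b)`` computes per-pair differences ``a - b`` (first minus
    second), the bias (mean difference), 95% limits of agreement
    ``bias ± 1.96 * SD(diff)`` (sample SD, ddof=1), the Pearson correlation,
    and the LoA half-width as a percentage of the reference mean.

    Parameters
    ----------
    agreement_multiple : float
        Multiple of SD(diff) defining the limits (default 1.96).
    """

    def __init__(self, agreement_multiple: float = Z95):
        self.agreement_multiple = agreement_multiple

    def fit(self, X, y, mean_a: float | None = None, mean_b: float | None = None) -> "BlandAltman":
        a = np.asarray(X, dtype=float).ravel()
        b = np.asarray(y, dtype=float).ravel()
        if a.size != b.size:
            raise ValueError("method vectors must have equal length")
        if a.size < 3:
            raise ValueError("need at least 3 paired observations")
        diffs = a - b
        self.bias_ = float(diffs.mean())
        self.sd_diff_ = float(np.std(diffs, ddof=1))
        half = self.agreement_multiple * self.sd_diff_
        self.loa_low_ = self.bias_ - half
        self.loa_high_ = self.bias_ + half
        ma = float(a.mean()) if mean_a is None else float(mean_a)
        mb = float(b.mean()) if mean_b is None else float(mean_b)
        self.reference_mean_ = 0.5 * (ma + mb)
        self.loa_pct_ = 100.0 * half / self.reference_mean_
        self.r_ = pearson_r(a, b) if (np.std(a) > 0 and np.std(b) > 0) else float("nan")
        self.means_ = 0.5 * (a + b)
        self.diffs_ = diffs
        self.n_ = int(a.size)
        return self

    def comparison_(self) -> MethodComparison:
        return MethodComparison(
            r=self.r_,
            bias=self.bias_,
            loa_low=self.loa_low_,
            loa_high=self.loa_high_,
            loa_pct=self.loa_pct_,
            reference_mean=self.reference_mean_,
            sd_diff=self.sd_diff_,
            n=self.n_,
            means=self.means_,
            diffs=self.diffs_,
        )


def bland_altman(a, b, mean_a: float | None = None, mean_b: float | None = None) -> MethodComparison:
    """Bland–Altman comparison (functional form); bias is ``mean(a - b)``.

    ``mean_a`` / ``mean_b`` override the reference group means used for the
    LoA%; by default the sample means of ``a`` and ``b`` are used.
    """
    return BlandAltman().fit(a, b, mean_a=mean_a, mean_b=mean_b).comparison_()
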