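"""Statistical layer: group comparison, correlation, reliability, and
threshold classification of tumour grade.

Group differences use the pooled-variance two-tailed Student's t-test
(df = n1 + n2 - 2); associations use Pearson's product-moment correlation;
reliability uses Cronbach's alpha and the two-way mixed, consistency,
single-measures intraclass correlation ICC(3,1); grade classification uses a
fixed concentration threshold with high grade as the positive class.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import PeridceError, ValidationError


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """Sizes, means and SDs of two groups."""

    n1: int
    m1: float
    sd1: float
    n2: int
    m2: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValidationError("standard deviations must be >= 0")

    @classmethod
    def from_samples(cls, x1, x2) -> "GroupSummary":
        x1 = np.asarray(x1, float)
        x2 = np.asarray(x2, float)
        return cls(x1.size, float(x1.mean()), float(x1.std(ddof=1)),
                   x2.size, float(x2.mean()), float(x2.std(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def students_t(summary: GroupSummary) -> TTestResult:
    """Pooled-variance two-tailed Student's t-test from group summaries."""
    sp2 = ((summary.n1 - 1) * summary.sd1 ** 2 + (summary.n2 - 1) * summary.sd2 ** 2)
    if sp2 <= 0:
        raise PeridceError("students_t: zero pooled variance")
    res = sps.ttest_ind_from_stats(
        summary.m1, summary.sd1, summary.n1,
        summary.m2, summary.sd2, summary.n2,
        equal_var=True,
    )
    return TTestResult(t=float(res.statistic), df=summary.n1 + summary.n2 - 2,
                       p=float(res.pvalue))


def percent_difference(m_high: float, m_low: float) -> float:
    """``100 * (m_high - m_low) / m_low`` reported to one decimal."""
    if m_low <= 0:
        raise ValidationError("percent_difference requires m_low > 0")
    return round(100.0 * (m_high - m_low) / m_low, 1)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-tailed t-based p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_r needs paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PeridceError("pearson_r: zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of a subjects x items table.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals),
    with unbiased (ddof=1) variances.  Anti-correlated items can yield
    alpha < 0; that is a property of the formula, not an error.
    """
    table = np.asarray(items, float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("cronbach_alpha needs >= 2 subjects and >= 2 items")
    k = table.shape[1]
    item_var = table.var(axis=0, ddof=1).sum()
    total_var = table.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise PeridceError("cronbach_alpha: zero variance of subject totals")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    df1: int
    df2: int
    p: float


def icc_consistency_single(ratings: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(3,1): two-way mixed effects, consistency, single measures.

    From the two-way ANOVA of a subjects x raters table,
    ``icc = (MS_rows - MS_error) / (MS_rows + (k - 1) MS_error)``; the
    confidence interval follows from the F statistic ``MS_rows / MS_error``.
    """
    table = np.asarray(ratings, float)
    if table.ndim != 2:
        raise ValidationError("ratings must be a subjects x raters table")
    n, k = table.shape
    if k < 2 or n < 5:
        raise ValidationError("icc needs >= 2 raters and >= 5 subjects")
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    df_rows, df_err = n - 1, (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err
    if ms_err < 0 or (ms_rows + (k - 1) * ms_err) == 0:
        raise PeridceError("icc: degenerate ANOVA decomposition")
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    if ms_err == 0:
        return IccResult(icc=1.0, ci_lower=1.0, ci_upper=1.0, df1=df_rows, df2=df_err, p=0.0)
    f_obs = ms_rows / ms_err
    fl = f_obs / sps.f.ppf(1 - alpha / 2, df_rows, df_err)
    fu = f_obs * sps.f.ppf(1 - alpha / 2, df_err, df_rows)
    p = float(sps.f.sf(f_obs, df_rows, df_err))
    return IccResult(
        icc=float(icc),
        ci_lower=float((fl - 1) / (fl + k - 1)),
        ci_upper=float((fu - 1) / (fu + k - 1)),
        df1=df_rows, df2=df_err, p=p,
    )


# ---------------------------------------------------------------------------
# threshold classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierMetrics:
    """Percent metrics of a fixed-threshold grade classifier."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int,
                           threshold: float = float("nan")) -> ClassifierMetrics:
    """All five percent metrics from an integer confusion matrix."""
    if min(tp, fn, tn, fp) < 0 or (tp + fn) == 0 or (tn + fp) == 0:
        raise ValidationError("confusion matrix needs both classes present")
    n = tp + fn + tn + fp
    return ClassifierMetrics(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / n,
        ppv=100.0 * tp / (tp + fp) if (tp + fp) else 0.0,
        npv=100.0 * tn / (tn + fn) if (tn + fn) else 0.0,
        threshold=threshold, tp=tp, fn=fn, tn=tn, fp=fp,
    )


def confusion_from_rates(sensitivity_pct: float, specificity_pct: float,
                         n_positive: int, n_negative: int) -> tuple[int, int, int, int]:
    """Reconstruct the integer confusion matrix behind printed rates.

    Returns ``(tp, fn, tn, fp)`` with counts rounded to the nearest integer;
    useful for checking the internal consistency of published
    sensitivity/specificity/PPV/accuracy tables.
    """
    tp = round(sensitivity_pct / 100.0 * n_positive)
    tn = round(specificity_pct / 100.0 * n_negative)
    return tp, n_positive - tp, tn, n_negative - tn


def threshold_classify(values, labels, threshold: float) -> ClassifierMetrics:
    """Classify high grade iff value > threshold (ties go to low grade)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    if values.size != labels.size:
        raise ValidationError("values and labels differ in length")
    if labels.all() or not labels.any():
        raise PeridceError("threshold_classify: both classes must be present")
    pred = values > threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    return metrics_from_confusion(tp, fn, tn, fp, threshold=threshold)
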