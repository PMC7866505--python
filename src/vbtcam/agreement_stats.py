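"""Instrument-agreement statistics for paired measurements.

Validating a practical instrument against a criterion produces, per
repetition, a pair of values for each variable (range, mean velocity, mean
force, mean power).  This module implements the standard method-comparison
toolkit for such pairs:

* ICC(2,1): two-way random-effects, absolute-agreement, single-measure
  intraclass correlation, from the two-way ANOVA mean squares, with the
  F-based 95% confidence interval;
* Cronbach's alpha for the two "items";
* paired t-test and mean difference with 95% CI;
* Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD of the
  differences), with an OLS regression of difference on mean to flag
  proportional bias (r^2 > 0.1);
* usefulness: the smallest worthwhile change (SWC, 0.2 x between-subject
  SD) against the typical error of measurement (SEM), whose ratio grades
  the instrument's ability to resolve meaningful changes;
* Pearson r with Fisher-z CI, and the standard error of estimate (SEE) of
  the criterion-on-practical regression, raw and standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "PairedMeasurements",
    "IccResult",
    "BlandAltmanResult",
    "UsefulnessResult",
    "PearsonSeeResult",
    "AgreementReport",
    "icc_2_1",
    "cronbach_alpha",
    "paired_difference",
    "bland_altman",
    "swc_sem_usefulness",
    "usefulness_ratio",
    "pearson_with_see",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-repetition values from two instruments for one variable.

    ``a`` is the practical (tested) instrument, ``b`` the criterion;
    ``subjects`` the per-repetition subject identifiers.
    """

    a: np.ndarray
    b: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float).ravel()
        b = np.asarray(self.b, dtype=float).ravel()
        if a.size != b.size:
            raise InputError("paired measurement columns differ in length")
        if a.size < 2:
            raise InputError("need at least 2 paired measurements")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if self.subjects is not None:
            s = np.asarray(self.subjects).ravel()
            if s.size != a.size:
                raise InputError("subject ids must match measurement length")
            object.__setattr__(self, "subjects", s)

    @property
    def n(self) -> int:
        return self.a.size


def _anova_mean_squares(a: np.ndarray, b: np.ndarray):
    """Two-way mean squares for an n x 2 (targets x raters) table."""
    table = np.column_stack([a, b])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


ICC_LABELS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


def _icc_label(value: float) -> str:
    for threshold, label in ICC_LABELS:
        if value > threshold:
            return label
    return "poor"


@dataclass(frozen=True)
class IccResult:
    value: float
    ci95: tuple[float, float]
    label: str
    msr: float = 0.0
    msc: float = 0.0
    mse: float = 0.0


def icc_2_1(pairs: PairedMeasurements, confidence: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random, absolute agreement, single measures.

    Point estimate from the ANOVA mean squares; the CI follows the F-based
    method with a Satterthwaite df for the lower/upper bounds.
    """
    if pairs.n < 3:
        raise InputError("ICC needs at least 3 repetitions")
    n, k, msr, msc, mse = _anova_mean_squares(pairs.a, pairs.b)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        raise InputError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 0:  # perfect agreement: CI collapses
        lo = hi = icc
    else:
        a_c = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b_c = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a_c):
            v = ((a_c * msc + b_c * mse) ** 2 /
                 ((a_c * msc) ** 2 / (k - 1) +
                  (b_c * mse) ** 2 / ((n - 1) * (k - 1))))
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_l * mse) /
                  (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_u * msr - mse) /
                  (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        else:
            lo = hi = 1.0
    return IccResult(value=float(icc), ci95=(float(lo), float(hi)),
                     label=_icc_label(float(icc)),
                     msr=float(msr), msc=float(msc), mse=float(mse))


def cronbach_alpha(pairs: PairedMeasurements) -> float:
    """Cronbach's alpha for the two instruments as items (k = 2)."""
    items = np.column_stack([pairs.a, pairs.b])
    k = items.shape[1]
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var < 1e-30:
        raise InputError("zero total variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def paired_difference(pairs: PairedMeasurements, confidence: float = 0.95):
    """Mean difference (a - b) with t-based CI and the paired-t p value."""
    d = pairs.a - pairs.b
    n = d.size
    mean = float(d.mean())
    if n < 2:
        raise InputError("need at least 2 pairs")
    se = d.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    if se > 0:
        t_stat, p = stats.ttest_rel(pairs.a, pairs.b)
    else:
        t_stat, p = np.inf if mean != 0 else 0.0, 0.0 if mean != 0 else 1.0
    return mean, (mean - tcrit * se, mean + tcrit * se), float(p)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r_squared: float
    proportional_bias: bool
    regression_defined: bool

    @property
    def loa_half_width(self) -> float:
        return 1.96 * self.sd_diff


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, 95% limits, proportional-bias check."""
    if pairs.n < 3:
        raise InputError("Bland-Altman needs at least 3 pairs")
    diff = pairs.a - pairs.b
    mean = (pairs.a + pairs.b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) < 1e-30:
        return BlandAltmanResult(bias=bias, sd_diff=sd,
                                 loa_low=bias - 1.96 * sd,
                                 loa_high=bias + 1.96 * sd,
                                 slope=np.nan, intercept=np.nan,
                                 r_squared=np.nan, proportional_bias=False,
                                 regression_defined=False)
    if sd < 1e-30:
        slope, intercept, r2 = 0.0, bias, 0.0
    else:
        res = stats.linregress(mean, diff)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue ** 2
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd,
                             slope=float(slope), intercept=float(intercept),
                             r_squared=float(r2),
                             proportional_bias=bool(r2 > 0.1),
                             regression_defined=True)


@dataclass(frozen=True)
class UsefulnessResult:
    swc: float
    sem: float
    ratio: float
    label: str


def usefulness_ratio(swc: float, sem: float) -> float:
    """SWC / SEM: the instrument's signal-to-noise for meaningful change."""
    if sem <= 0:
        raise InputError("SEM must be positive")
    return swc / sem


def _usefulness_label(ratio: float) -> str:
    if ratio > 1.0:
        return "good"
    if ratio == 1.0:
        return "satisfactory"
    return "marginal"


def swc_sem_usefulness(pairs: PairedMeasurements,
                       sem_method: str = "difference") -> UsefulnessResult:
    """Smallest worthwhile change vs typical error of measurement.

    SWC = 0.2 x SD of subject means (between-subject SD); SEM, by the
    default difference-score convention, is SD(a - b) / sqrt(2); the
    alternative ``sem_method='anova'`` uses sqrt(MS_error) from the ICC
    two-way ANOVA.
    """
    if pairs.subjects is None:
        raise InputError("subject ids are required for the SWC")
    subjects = np.asarray(pairs.subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise InputError("SWC undefined with a single subject")
    pooled = (pairs.a + pairs.b) / 2.0
    subj_means = np.array([pooled[subjects == s].mean() for s in uniq])
    swc = 0.2 * float(subj_means.std(ddof=1))
    if sem_method == "difference":
        sem = float((pairs.a - pairs.b).std(ddof=1) / np.sqrt(2.0))
    elif sem_method == "anova":
        _, _, _, _, mse = _anova_mean_squares(pairs.a, pairs.b)
        sem = float(np.sqrt(mse))
    else:
        raise InputError(f"unknown sem_method {sem_method!r}")
    ratio = usefulness_ratio(swc, sem)
    return UsefulnessResult(swc=swc, sem=sem, ratio=ratio,
                            label=_usefulness_label(ratio))


SEE_LABELS = ((2.0, "extremely large"), (1.0, "very large"), (0.6, "large"),
              (0.3, "moderate"), (0.1, "small"))


def _see_label(standardized: float) -> str:
    for threshold, label in SEE_LABELS:
        if standardized >= threshold:
            return label
    return "trivial"


@dataclass(frozen=True)
class PearsonSeeResult:
    r: float
    r_ci95: tuple[float, float]
    see: float
    see_standardized: float
    see_label: str
    slope: float
    intercept: float


def pearson_with_see(pairs: PairedMeasurements,
                     confidence: float = 0.95) -> PearsonSeeResult:
    """Pearson r (Fisher-z CI) and the SEE of regressing a on b.

    SEE is the residual SD of the OLS fit of the practical instrument on
    the criterion; standardized SEE divides by SD(a) and is labelled on the
    halved modified-Cohen scale.
    """
    a, b = pairs.a, pairs.b
    n = pairs.n
    if n < 3:
        raise InputError("need at least 3 pairs")
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    if sd_a < 1e-30 or sd_b < 1e-30:
        raise InputError("zero variance in one column: r undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    z = np.arctanh(r_clip)
    zse = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + confidence / 2)
    ci = (float(np.tanh(z - zcrit * zse)), float(np.tanh(z + zcrit * zse)))
    res = stats.linregress(b, a)
    resid = a - (res.slope * b + res.intercept)
    see = float(np.sqrt(np.sum(resid ** 2) / (n - 2)))
    std_see = see / float(sd_a)
    return PearsonSeeResult(r=r, r_ci95=ci, see=see,
                            see_standardized=std_see,
                            see_label=_see_label(std_see),
                            slope=float(res.slope),
                            intercept=float(res.intercept))


@dataclass
class AgreementReport:
    """All agreement statistics for one paired variable."""

    icc: IccResult
    cronbach_alpha: float
    mean_difference: float
    mean_difference_ci95: tuple[float, float]
    paired_t_p: float
    bland_altman: BlandAltmanResult
    usefulness: UsefulnessResult | None
    pearson_see: PearsonSeeResult

    def to_dict(self) -> dict:
        out = {
            "icc": self.icc.value, "icc_ci95": list(self.icc.ci95),
            "icc_label": self.icc.label,
            "cronbach_alpha": self.cronbach_alpha,
            "mean_difference": self.mean_difference,
            "mean_difference_ci95": list(self.mean_difference_ci95),
            "paired_t_p": self.paired_t_p,
            "bias": self.bland_altman.bias,
            "random_error": self.bland_altman.loa_half_width,
            "loa": [self.bland_altman.loa_low, self.bland_altman.loa_high],
            "proportional_bias_r2": self.bland_altman.r_squared,
            "proportional_bias": self.bland_altman.proportional_bias,
            "pearson_r": self.pearson_see.r,
            "pearson_r_ci95": list(self.pearson_see.r_ci95),
            "see": self.pearson_see.see,
            "see_standardized": self.pearson_see.see_standardized,
            "see_label": self.pearson_see.see_label,
        }
        if self.usefulness is not None:
            out.update({"swc": self.usefulness.swc, "sem": self.usefulness.sem,
                        "swc_sem_ratio": self.usefulness.ratio,
                        "usefulness_label": self.usefulness.label})
        return out


def agreement_report(pairs: PairedMeasurements,
                     sem_method: str = "difference") -> AgreementReport:
    """Full instrument-agreement report for one variable."""
    mean_diff, ci, p = paired_difference(pairs)
    usefulness = (swc_sem_usefulness(pairs, sem_method)
                  if pairs.subjects is not None else None)
    return AgreementReport(
        icc=icc_2_1(pairs),
        cronbach_alpha=cronbach_alpha(pairs),
        mean_difference=mean_diff,
        mean_difference_ci95=ci,
        paired_t_p=p,
        bland_altman=bland_altman(pairs),
        usefulness=usefulness,
        pearson_see=pearson_with_see(pairs),
    )
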