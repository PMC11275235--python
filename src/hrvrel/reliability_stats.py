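"""Test-retest reliability statistics for paired (day 1 vs day 7) trials.

Absolute reliability follows the Hopkins difference-score approach: the
typical error of measurement (TEM) is the standard deviation of the
test-retest differences divided by sqrt(2); expressed as a percentage of
the grand mean it is the TEM% — the same quantity usually reported as the
coefficient of variation (CV).  Relative reliability is the Pearson
product-moment correlation.  Both carry 90 % confidence intervals: the TEM
interval comes from the chi-square distribution of the error variance with
n-1 degrees of freedom, the correlation interval from the Fisher
z-transform with standard error 1/sqrt(n-3).

Qualitative bins: CV < 5 % low, 5-10 % moderate, > 10 % high (the
boundaries 5 and 10 fall in "moderate"); r < 0.5 poor, 0.5-0.75 moderate,
0.75-0.9 good, >= 0.9 excellent (each boundary goes to the higher class —
the source wording is ambiguous at exact boundaries, so the convention is
fixed here and documented).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PairedTrials",
    "ReliabilityResult",
    "typical_error",
    "tem_confidence_interval",
    "pearson_with_ci",
    "classify_cv",
    "classify_r",
    "paired_ttest",
    "sample_size_pearson",
    "reliability_result",
]


@dataclass
class PairedTrials:
    """Two trials of one parameter for the same subjects, same units."""

    subject_ids: list[str]
    trial1: np.ndarray
    trial2: np.ndarray

    def __post_init__(self) -> None:
        self.trial1 = np.asarray(self.trial1, dtype=float)
        self.trial2 = np.asarray(self.trial2, dtype=float)
        if not (len(self.subject_ids) == self.trial1.size == self.trial2.size):
            raise ValueError("subject_ids, trial1 and trial2 must have equal length")
        ok = np.isfinite(self.trial1) & np.isfinite(self.trial2)
        if not ok.all():
            dropped = [s for s, k in zip(self.subject_ids, ok) if not k]
            logger.info("listwise deletion of %d subject(s) with missing trials: %s",
                        len(dropped), dropped)
            self.subject_ids = [s for s, k in zip(self.subject_ids, ok) if k]
            self.trial1 = self.trial1[ok]
            self.trial2 = self.trial2[ok]

    @property
    def n(self) -> int:
        return self.trial1.size

    @property
    def differences(self) -> np.ndarray:
        return self.trial2 - self.trial1


@dataclass
class ReliabilityResult:
    """Absolute + relative reliability of one parameter, Table-row shaped."""

    parameter: str
    n: int
    tem: float
    tem_ci90: tuple[float, float]
    tem_pct: float
    tem_pct_ci90: tuple[float, float]
    pearson_r: float
    r_ci90: tuple[float, float]
    cv_class: str
    r_class: str


def typical_error(pairs: PairedTrials) -> tuple[float, float]:
    """TEM = SD(diff)/sqrt(2) and TEM% = 100*TEM / grand mean.

    The grand mean pools all 2n observations.  TEM% is NaN (flagged
    undefined) when the grand mean is not positive.
    """
    if pairs.n < 3:
        raise ValueError("typical error needs at least 3 paired subjects")
    d = pairs.differences
    tem = float(np.std(d, ddof=1)) / math.sqrt(2.0)
    grand_mean = float(np.mean(np.concatenate([pairs.trial1, pairs.trial2])))
    if grand_mean <= 0:
        logger.warning("grand mean %.4g <= 0: TEM%% undefined", grand_mean)
        return tem, math.nan
    return tem, 100.0 * tem / grand_mean


def tem_confidence_interval(tem: float, n: int, level: float = 0.90) -> tuple[float, float]:
    """Chi-square CI for the typical error with df = n - 1.

    lower = tem*sqrt(df/chi2_{1-a/2,df}), upper = tem*sqrt(df/chi2_{a/2,df});
    the upper/lower ratio depends only on n.
    """
    if n < 3:
        raise ValueError("confidence interval needs n >= 3")
    if tem < 0:
        raise ValueError("tem must be non-negative")
    if tem == 0:
        return (0.0, 0.0)
    df = n - 1
    alpha = 1.0 - level
    lo = tem * math.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
    hi = tem * math.sqrt(df / stats.chi2.ppf(alpha / 2, df))
    return (lo, hi)


def pearson_with_ci(
    pairs: PairedTrials, level: float = 0.90
) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher-z confidence interval.

    CI bounds are tanh(atanh(r) -/+ z*/sqrt(n-3)).  Perfectly correlated
    trials return r = 1 with the degenerate interval (1, 1).
    """
    if pairs.n < 4:
        raise ValueError("Pearson CI needs at least 4 paired subjects")
    if np.std(pairs.trial1) == 0 or np.std(pairs.trial2) == 0:
        raise ValueError("degenerate trial vector (zero variance)")
    r = float(np.corrcoef(pairs.trial1, pairs.trial2)[0, 1])
    if abs(r) >= 1.0:
        r = math.copysign(1.0, r)
        return r, (r, r)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    z = math.atanh(r)
    half = zcrit / math.sqrt(pairs.n - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


def classify_cv(cv_pct: float) -> str:
    """Absolute-reliability bin: <5 low, 5-10 moderate (inclusive), >10 high."""
    if math.isnan(cv_pct):
        raise ValueError("cv undefined")
    if cv_pct < 5.0:
        return "low"
    if cv_pct <= 10.0:
        return "moderate"
    return "high"


def classify_r(r: float) -> str:
    """Relative-reliability bin; boundaries 0.5/0.75/0.9 go to the higher class."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if r < 0.5:
        return "poor"
    if r < 0.75:
        return "moderate"
    if r < 0.9:
        return "good"
    return "excellent"


def paired_ttest(pairs: PairedTrials) -> tuple[float, int, float]:
    """Paired t-test of trial2 vs trial1: (t, df, two-sided p).

    A perfectly reproduced trial (all differences zero) reports t = 0,
    p = 1 with a note; a constant non-zero difference has no within-pair
    variance and is an error.
    """
    if pairs.n < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    d = pairs.differences
    sd = float(np.std(d, ddof=1))
    df = pairs.n - 1
    if sd == 0.0:
        if float(np.mean(d)) == 0.0:
            logger.info("all differences zero: reporting t=0, p=1")
            return 0.0, df, 1.0
        raise ValueError("zero variance of differences with non-zero mean shift")
    t = float(np.mean(d)) / (sd / math.sqrt(pairs.n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def sample_size_pearson(
    r: float, alpha: float = 0.05, power: float = 0.90, sides: int = 2
) -> int:
    """Minimum n to detect correlation r, by the Fisher-z approximation.

    n = ceil(((z_crit + z_power)/atanh(r))^2 + 3), floored at 4.  Note that
    at r = 0.70, alpha = 0.05, power = 0.90 this standard formula gives 17
    (two-sided) or 15 (one-sided), not the 13 sometimes quoted for those
    inputs; see the methods note.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie strictly in (0, 1)")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    z_crit = stats.norm.ppf(1 - alpha / sides)
    z_pow = stats.norm.ppf(power)
    n = math.ceil(((z_crit + z_pow) / math.atanh(r)) ** 2 + 3)
    return max(n, 4)


def reliability_result(
    pairs: PairedTrials, parameter: str = "", level: float = 0.90
) -> ReliabilityResult:
    """Full reliability block for one parameter: TEM, TEM%/CV, r, CIs, bins."""
    tem, tem_pct = typical_error(pairs)
    tem_ci = tem_confidence_interval(tem, pairs.n, level)
    if math.isnan(tem_pct):
        tem_pct_ci = (math.nan, math.nan)
        cv_class = "undefined"
    else:
        tem_pct_ci = tem_confidence_interval(tem_pct, pairs.n, level)
        cv_class = classify_cv(tem_pct)
    r, r_ci = pearson_with_ci(pairs, level)
    return ReliabilityResult(
        parameter=parameter,
        n=pairs.n,
        tem=tem,
        tem_ci90=tem_ci,
        tem_pct=tem_pct,
        tem_pct_ci90=tem_pct_ci,
        pearson_r=r,
        r_ci90=r_ci,
        cv_class=cv_class,
        r_class=classify_r(r),
    )
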