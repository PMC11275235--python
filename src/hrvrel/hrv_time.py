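"""Time-domain heart rate variability metrics.

All statistics operate on a corrected R-R series (normal-to-normal
intervals).  Conventions: SDNN uses the sample (n-1) standard deviation;
RMSSD averages the squared successive differences over the n-1 difference
pairs; pNN50 counts differences strictly greater than 50 ms; mean heart
rate is the mean of per-beat instantaneous rates 60000/RR_i (the common
HRV-software convention), with the reciprocal-of-mean-RR alternative
exposed as a secondary field.  The log transform applied to RMSSD is the
natural logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rr_io import RRSeries

__all__ = ["TimeDomainMetrics", "time_domain", "NN_THRESHOLD_MS"]

NN_THRESHOLD_MS = 50.0


@dataclass
class TimeDomainMetrics:
    mean_rr_ms: float
    mean_hr_bpm: float
    #: 60000 / mean RR — the alternative heart-rate convention
    mean_hr_from_mean_rr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    #: natural log of RMSSD; NaN when RMSSD is exactly zero
    rmssd_ln: float
    nn50: int
    pnn50_pct: float
    n_beats: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_rr_ms": self.mean_rr_ms,
            "mean_hr_bpm": self.mean_hr_bpm,
            "sdnn_ms": self.sdnn_ms,
            "rmssd_ms": self.rmssd_ms,
            "rmssd_ln": self.rmssd_ln,
            "nn50": float(self.nn50),
            "pnn50_pct": self.pnn50_pct,
        }


def time_domain(series: RRSeries) -> TimeDomainMetrics:
    """Compute mean RR/HR, SDNN, RMSSD (+ln), NN50 and pNN50.

    Requires at least 2 beats; pNN50 is defined over the n-1 successive
    difference pairs.
    """
    iv = series.intervals_ms
    n = iv.size
    if n < 2:
        raise ValueError("insufficient beats: time-domain metrics need >= 2 intervals")
    diffs = np.diff(iv)
    mean_rr = float(np.mean(iv))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    nn50 = int(np.sum(np.abs(diffs) > NN_THRESHOLD_MS))
    return TimeDomainMetrics(
        mean_rr_ms=mean_rr,
        mean_hr_bpm=float(np.mean(60000.0 / iv)),
        mean_hr_from_mean_rr_bpm=60000.0 / mean_rr,
        sdnn_ms=float(np.std(iv, ddof=1)),
        rmssd_ms=rmssd,
        rmssd_ln=math.log(rmssd) if rmssd > 0 else math.nan,
        nn50=nn50,
        pnn50_pct=100.0 * nn50 / (n - 1),
        n_beats=n,
    )
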