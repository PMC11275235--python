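"""Frequency-domain HRV via autoregressive (Burg) spectral analysis.

The unevenly sampled R-R tachogram is interpolated with a cubic spline,
resampled on an even grid (default 4 Hz), optionally linearly detrended,
fitted with an AR model by Burg's method (default order 16), and the
resulting power spectral density integrated over the conventional
short-term bands: VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz.

Children can breathe faster than 0.4 Hz; the HF upper edge is therefore a
configuration field, not a constant.  Recordings shorter than 60 s are
refused outright — spectral indices on 30 s windows are not meaningful and
the recovery windows of the protocol are analysed in the time domain only.
A warning is logged below 240 s, the conventional minimum for a stable LF
estimate.

Band powers are reported in ms^2 with natural-log companions, as percent of
total power, and in normalized units defined on the LF+HF subtotal
(lf_nu + hf_nu = 100 by construction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import detrend as _detrend
from statsmodels.regression.linear_model import burg as _burg

from .rr_io import RRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralConfig",
    "FreqDomainMetrics",
    "resample_tachogram",
    "ar_spectrum",
    "band_powers",
    "frequency_domain",
]

MIN_DURATION_S = 60.0
RECOMMENDED_DURATION_S = 240.0


@dataclass(frozen=True)
class SpectralConfig:
    resample_hz: float = 4.0
    ar_order: int = 16
    detrend: str = "linear"  # "none" or "linear"
    vlf_band: tuple[float, float] = (0.003, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    # PSD grid points over [0, resample_hz/2]; AR peaks are narrow, so band
    # integrals need a dense grid to converge (see methods note)
    n_freq: int = 16385

    def __post_init__(self) -> None:
        if self.resample_hz <= 0:
            raise ValueError("resample_hz must be positive")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.detrend not in ("none", "linear"):
            raise ValueError("detrend must be 'none' or 'linear'")
        edges = [*self.vlf_band, *self.lf_band, *self.hf_band]
        if any(b <= a for a, b in (self.vlf_band, self.lf_band, self.hf_band)):
            raise ValueError("each band must have lower < upper edge")
        if edges != sorted(edges):
            raise ValueError("bands must be increasing and non-overlapping")
        if self.hf_band[1] > self.resample_hz / 2:
            raise ValueError("HF upper edge exceeds the resampling Nyquist frequency")
        if self.n_freq < 1024:
            raise ValueError("n_freq must be >= 1024 for stable band integrals")

    def with_hf_upper(self, hz: float) -> "SpectralConfig":
        """Convenience for the paediatric fast-breathing override."""
        return replace(self, hf_band=(self.hf_band[0], hz))


@dataclass
class FreqDomainMetrics:
    vlf_ms2: float
    lf_ms2: float
    hf_ms2: float
    total_power_ms2: float
    lf_ln: float
    hf_ln: float
    tp_ln: float
    lf_nu: float
    hf_nu: float
    lf_hf_ratio: float
    lf_pct: float
    hf_pct: float
    config: SpectralConfig = field(repr=False, default_factory=SpectralConfig)

    def as_dict(self) -> dict[str, float]:
        return {
            "vlf_ms2": self.vlf_ms2,
            "lf_ms2": self.lf_ms2,
            "hf_ms2": self.hf_ms2,
            "total_power_ms2": self.total_power_ms2,
            "lf_ln": self.lf_ln,
            "hf_ln": self.hf_ln,
            "tp_ln": self.tp_ln,
            "lf_nu": self.lf_nu,
            "hf_nu": self.hf_nu,
            "lf_hf_ratio": self.lf_hf_ratio,
            "lf_pct": self.lf_pct,
            "hf_pct": self.hf_pct,
        }


def resample_tachogram(
    series: RRSeries, config: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resample RR(t) by cubic-spline interpolation.

    Returns ``(t_s, rr_ms)`` sampled at ``config.resample_hz`` over
    ``[t_end_s[0], t_end_s[-1]]``, detrended per the config.  Refuses
    recordings shorter than 60 s.
    """
    span = series.t_end_s[-1] - series.t_end_s[0]
    if series.duration_s < MIN_DURATION_S:
        raise ValueError(
            f"recording of {series.duration_s:.1f} s is too short for frequency "
            f"analysis (minimum {MIN_DURATION_S:.0f} s); use time-domain metrics"
        )
    if series.duration_s < RECOMMENDED_DURATION_S:
        logger.warning(
            "recording of %.1f s is below the %.0f s recommended for a stable LF estimate",
            series.duration_s, RECOMMENDED_DURATION_S,
        )
    if series.n_beats < 4:
        raise ValueError("cubic-spline resampling needs at least 4 beats")
    spline = CubicSpline(series.t_end_s, series.intervals_ms)
    n = int(math.floor(span * config.resample_hz)) + 1
    t = series.t_end_s[0] + np.arange(n) / config.resample_hz
    rr = spline(t)
    if config.detrend == "linear":
        rr = _detrend(rr, type="linear")
    return t, rr


def ar_spectrum(
    signal: np.ndarray, config: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided AR (Burg) power spectral density of an evenly sampled signal.

    Returns ``(freq_hz, psd_ms2_per_hz)`` on a ``config.n_freq``-point grid
    over [0, Nyquist].  The mean is removed before fitting, so the integral
    of the PSD approximates the signal variance (Parseval property of the
    AR model).  An unstable fit (AR poles on or outside the unit circle)
    raises with advice to lower the order.
    """
    x = np.asarray(signal, dtype=float)
    if x.size <= 2 * config.ar_order:
        raise ValueError(
            f"signal of {x.size} samples too short for AR order {config.ar_order}"
        )
    fs = config.resample_hz
    if np.ptp(x) == 0.0:
        # constant signal carries no oscillatory power
        f = np.linspace(0.0, fs / 2, config.n_freq)
        return f, np.zeros_like(f)
    rho, sigma2 = _burg(x, order=config.ar_order, demean=True)
    roots = np.roots(np.r_[1.0, -rho])
    if np.any(np.abs(roots) >= 1.0):
        raise ValueError(
            "ill-conditioned AR fit (pole on/outside the unit circle); "
            "lower ar_order or lengthen the recording"
        )
    f = np.linspace(0.0, fs / 2, config.n_freq)
    k = np.arange(1, config.ar_order + 1)
    transfer = 1.0 - np.exp(-2j * np.pi * np.outer(f, k) / fs) @ rho
    psd = 2.0 * sigma2 / fs / np.abs(transfer) ** 2
    return f, psd


def band_powers(
    freq_hz: np.ndarray,
    psd: np.ndarray,
    config: SpectralConfig = SpectralConfig(),
) -> FreqDomainMetrics:
    """Integrate the PSD over VLF/LF/HF and derive the standard summaries.

    Trapezoidal integration over each band; total power is VLF+LF+HF;
    normalized units are defined on the LF+HF subtotal.  With zero total
    power the ratios and normalized units are NaN (flagged undefined).
    """

    def _band(lo: float, hi: float) -> float:
        mask = (freq_hz >= lo) & (freq_hz <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freq_hz[mask]))

    vlf = _band(*config.vlf_band)
    lf = _band(*config.lf_band)
    hf = _band(*config.hf_band)
    total = vlf + lf + hf
    lfhf = lf + hf
    nan = float("nan")
    return FreqDomainMetrics(
        vlf_ms2=vlf,
        lf_ms2=lf,
        hf_ms2=hf,
        total_power_ms2=total,
        lf_ln=math.log(lf) if lf > 0 else nan,
        hf_ln=math.log(hf) if hf > 0 else nan,
        tp_ln=math.log(total) if total > 0 else nan,
        lf_nu=100.0 * lf / lfhf if lfhf > 0 else nan,
        hf_nu=100.0 * hf / lfhf if lfhf > 0 else nan,
        lf_hf_ratio=lf / hf if hf > 0 else nan,
        lf_pct=100.0 * lf / total if total > 0 else nan,
        hf_pct=100.0 * hf / total if total > 0 else nan,
        config=config,
    )


def frequency_domain(
    series: RRSeries, config: SpectralConfig = SpectralConfig()
) -> FreqDomainMetrics:
    """Resample, fit the AR spectrum and integrate the bands in one call."""
    _, rr = resample_tachogram(series, config)
    f, psd = ar_spectrum(rr, config)
    return band_powers(f, psd, config)
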