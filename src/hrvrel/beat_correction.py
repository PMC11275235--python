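"""Ectopic / missed-beat artifact detection and correction.

Aberrant beats are found by comparison against a local running median and
replaced, never deleted: an abnormally long interval (tagged ``high``) is
replaced by the mean of its two neighbours, an abnormally short one
(tagged ``low``) by the previous interval.  A recording in which more than
20 % of beats needed correction is marked as failing the inclusion
criterion and should be excluded from analysis.

The detector is deliberately simple: beat ``i`` is flagged when it deviates
by more than ``rel_threshold`` (default 25 %) from the median of the
``window`` beats centred on it.  The median window includes the beat
itself — the median is robust to the one candidate outlier, and inclusion
keeps the rule well behaved at the series edges where the window truncates.
The threshold is a free parameter, not a physiological constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rr_io import RRSeries

logger = logging.getLogger(__name__)

__all__ = ["CorrectionReport", "flag_artifacts", "correct_artifacts", "correct_series"]

DEFAULT_THRESHOLD = 0.25
DEFAULT_WINDOW = 11
DEFAULT_MAX_FRACTION = 0.20


@dataclass
class CorrectionReport:
    """Outcome of one correction pass over one recording segment."""

    corrected_series: RRSeries
    n_flagged_high: int
    n_flagged_low: int
    corrected_fraction: float
    included: bool
    #: (index, original ms, replacement ms, rule tag) for every corrected beat
    per_beat_log: list[tuple[int, float, float, str]]

    def log_frame(self) -> pd.DataFrame:
        """Correction log as a table (index, original, replacement, rule)."""
        return pd.DataFrame(
            self.per_beat_log, columns=["index", "original_ms", "replacement_ms", "rule"]
        )


def _local_medians(iv: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = iv.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(iv[lo:hi])
    return out


def flag_artifacts(
    series: RRSeries,
    rel_threshold: float = DEFAULT_THRESHOLD,
    window: int = DEFAULT_WINDOW,
) -> dict[int, str]:
    """Flag beats deviating more than ``rel_threshold`` from the local median.

    Returns a mapping of beat index to direction tag: ``"high"`` for
    intervals above ``(1+rel_threshold)`` times the local median (candidate
    ectopic-type artifact per the correction rules), ``"low"`` for intervals
    below ``(1-rel_threshold)`` times it.  The window truncates at the
    series edges.
    """
    if rel_threshold <= 0:
        raise ValueError("rel_threshold must be positive")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if series.n_beats < 3:
        raise ValueError("too short to assess artifacts (need at least 3 beats)")
    iv = series.intervals_ms
    med = _local_medians(iv, window)
    flags: dict[int, str] = {}
    for i in np.flatnonzero(iv > (1.0 + rel_threshold) * med):
        flags[int(i)] = "high"
    for i in np.flatnonzero(iv < (1.0 - rel_threshold) * med):
        flags[int(i)] = "low"
    return dict(sorted(flags.items()))


def correct_artifacts(
    series: RRSeries,
    flags: dict[int, str],
    max_fraction: float = DEFAULT_MAX_FRACTION,
) -> CorrectionReport:
    """Replace flagged beats and report the corrected fraction.

    Replacement uses the ORIGINAL neighbour values in a single pass (no
    cascade), so the operation is deterministic and order independent:

    * ``high`` — replaced by the mean of the two adjacent original intervals;
      at the first/last beat the single available neighbour is used (logged).
    * ``low`` — replaced by the previous original interval; at index 0 the
      next interval is used instead (logged).

    ``included`` is True when the corrected fraction does not exceed
    ``max_fraction`` (default 20 % of the recording).
    """
    iv = series.intervals_ms
    n = iv.size
    corrected = iv.copy()
    per_beat_log: list[tuple[int, float, float, str]] = []
    n_high = n_low = 0
    for i, tag in sorted(flags.items()):
        if not 0 <= i < n:
            raise IndexError(f"flag index {i} outside series of {n} beats")
        if tag == "high":
            if 0 < i < n - 1:
                repl = (iv[i - 1] + iv[i + 1]) / 2.0
            else:
                repl = iv[i + 1] if i == 0 else iv[i - 1]
                logger.info("high flag at edge index %d: single neighbour used", i)
            n_high += 1
        elif tag == "low":
            if i > 0:
                repl = iv[i - 1]
            else:
                repl = iv[1]
                logger.info("low flag at index 0: next interval used as fallback")
            n_low += 1
        else:
            raise ValueError(f"unknown rule tag {tag!r} at index {i}")
        corrected[i] = repl
        per_beat_log.append((i, float(iv[i]), float(repl), tag))
    fraction = (n_high + n_low) / n
    return CorrectionReport(
        corrected_series=RRSeries(corrected, label=series.label),
        n_flagged_high=n_high,
        n_flagged_low=n_low,
        corrected_fraction=fraction,
        included=fraction <= max_fraction,
        per_beat_log=per_beat_log,
    )


def correct_series(
    series: RRSeries,
    rel_threshold: float = DEFAULT_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    max_fraction: float = DEFAULT_MAX_FRACTION,
) -> CorrectionReport:
    """Convenience: flag then correct in one call."""
    flags = flag_artifacts(series, rel_threshold=rel_threshold, window=window)
    return correct_artifacts(series, flags, max_fraction=max_fraction)
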