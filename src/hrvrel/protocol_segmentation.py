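"""Mapping session streams onto the at-home protocol and step-test physiology.

The protocol is: 5 min seated rest, then a sub-maximal step test consisting
of a 30 s standing stabilisation period, 3 min of stepping at 88 steps/min,
and 2 min of still standing recovery.  The recovery phase is analysed in
four 30 s windows anchored at the end of the last stepping beat, using the
half-open convention [30w, 30(w+1)) on beat end times.

Step-test intensity is summarised as the percentage of age-predicted
maximal heart rate, using the Tanaka estimate MHR = 208 - 0.7 x age, the
most accurate age prediction in children.  A VO2max prediction equation is
deliberately a pluggable hook (register your preferred equation); step
height comes from a stature-keyed lookup table supplied as configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .hrv_time import time_domain
from .rr_io import RRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolWindows",
    "StepTestResult",
    "segment_recovery",
    "tanaka_mhr",
    "pct_mhr",
    "register_vo2max_equation",
    "predicted_vo2max",
    "step_height_from_table",
    "RECOVERY_WINDOW_S",
    "N_RECOVERY_WINDOWS",
    "STEP_CADENCE_PER_MIN",
    "PHASE_DURATIONS_S",
]

RECOVERY_WINDOW_S = 30.0
N_RECOVERY_WINDOWS = 4
#: metronome cadence of the stepping phase (protocol metadata only)
STEP_CADENCE_PER_MIN = 88
PHASE_DURATIONS_S = {"rest": 300.0, "stabilisation": 30.0, "stepping": 180.0, "recovery": 120.0}


@dataclass
class ProtocolWindows:
    rest: RRSeries | None = None
    stabilisation: RRSeries | None = None
    stepping: RRSeries | None = None
    recovery_windows: list[RRSeries] = field(default_factory=list)


@dataclass
class StepTestResult:
    age_predicted_mhr_bpm: float
    mean_exercise_hr_bpm: float
    pct_mhr: float
    predicted_vo2max_ml_kg_min: float | None = None
    step_height_cm: float | None = None


def segment_recovery(
    recovery: RRSeries,
    window_s: float = RECOVERY_WINDOW_S,
    n_windows: int = N_RECOVERY_WINDOWS,
) -> list[RRSeries]:
    """Split the recovery stream into 30 s windows from recovery onset.

    Onset is the start of the stream (the end time of the last stepping
    beat); a beat belongs to window ``w`` iff its end time lies in
    ``[w*window_s, (w+1)*window_s)``.  Beats ending at or past the last
    boundary are dropped.  A stream shorter than the full 2 min yields as
    many complete windows as fit, with a logged warning.
    """
    if recovery.n_beats == 0:  # unreachable through RRSeries, kept for contract clarity
        raise ValueError("empty recovery stream")
    total = n_windows * window_s
    n_complete = n_windows
    if recovery.duration_s < total:
        n_complete = int(recovery.duration_s // window_s)
        logger.warning(
            "recovery stream covers %.1f s < %.0f s: only %d complete window(s)",
            recovery.duration_s, total, n_complete,
        )
        if n_complete == 0:
            raise ValueError(
                f"recovery stream of {recovery.duration_s:.1f} s shorter than one "
                f"{window_s:.0f} s window"
            )
    windows = []
    for w in range(n_complete):
        windows.append(
            recovery.slice_time(
                w * window_s, (w + 1) * window_s,
                label=f"{recovery.label}[{int(w * window_s)}-{int((w + 1) * window_s)}s]",
            )
        )
    return windows


def tanaka_mhr(age_years: float) -> float:
    """Age-predicted maximal heart rate, 208 - 0.7 x age (bpm)."""
    if age_years <= 0:
        raise ValueError("age must be positive")
    return 208.0 - 0.7 * age_years


def pct_mhr(stepping: RRSeries, age_years: float) -> float:
    """Mean exercise HR as a percentage of the Tanaka age-predicted maximum."""
    mean_hr = time_domain(stepping).mean_hr_bpm
    return 100.0 * mean_hr / tanaka_mhr(age_years)


# --- pluggable VO2max prediction -------------------------------------------

_VO2MAX_EQUATIONS: dict[str, Callable[..., float]] = {}


def register_vo2max_equation(name: str, fn: Callable[..., float]) -> None:
    """Register a VO2max prediction equation under ``name``.

    The callable receives keyword arguments (at least ``mean_exercise_hr_bpm``,
    plus whatever subject covariates the caller passes) and returns ml/kg/min.
    """
    _VO2MAX_EQUATIONS[name] = fn


def predicted_vo2max(name: str | None = None, **inputs) -> float | None:
    """Apply a registered prediction equation; None (with a notice) if absent."""
    if name is None or name not in _VO2MAX_EQUATIONS:
        logger.info(
            "no VO2max prediction equation registered%s; skipping",
            f" under {name!r}" if name else "",
        )
        return None
    return float(_VO2MAX_EQUATIONS[name](**inputs))


def step_height_from_table(height_m: float, table: dict[float, float]) -> float:
    """Step height (cm) from a stature-keyed config table.

    ``table`` maps stature thresholds in metres to step heights in cm; the
    entry with the largest threshold not exceeding the subject's height is
    used.  A height below every threshold is an error.
    """
    if not table:
        raise ValueError("empty step-height table")
    thresholds = sorted(table)
    eligible = [t for t in thresholds if t <= height_m]
    if not eligible:
        raise ValueError(
            f"height {height_m} m below the smallest table threshold {thresholds[0]} m"
        )
    return float(table[eligible[-1]])


def step_test_summary(
    stepping: RRSeries,
    age_years: float,
    vo2max_equation: str | None = None,
    height_m: float | None = None,
    step_height_table: dict[float, float] | None = None,
    **vo2max_inputs,
) -> StepTestResult:
    """Assemble the step-test physiology block for one session."""
    mhr = tanaka_mhr(age_years)
    mean_hr = time_domain(stepping).mean_hr_bpm
    vo2 = predicted_vo2max(
        vo2max_equation, mean_exercise_hr_bpm=mean_hr, age_years=age_years, **vo2max_inputs
    )
    height = None
    if step_height_table is not None and height_m is not None:
        height = step_height_from_table(height_m, step_height_table)
    return StepTestResult(
        age_predicted_mhr_bpm=mhr,
        mean_exercise_hr_bpm=mean_hr,
        pct_mhr=100.0 * mean_hr / mhr,
        predicted_vo2max_ml_kg_min=vo2,
        step_height_cm=height,
    )


__all__.append("step_test_summary")
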