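"""Reading, writing and validating R-R interval series and session metadata.

The on-disk dialect is the plain-text export common to consumer HRV apps:
one R-R interval in milliseconds per line.  An optional single header line
(anything not starting with a digit, sign or decimal point) is skipped with
a logged notice, since exports from phone apps sometimes carry one.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RRSeries",
    "SubjectRecord",
    "SessionRecord",
    "read_rr_text",
    "write_rr_text",
    "validate_physiology",
    "read_manifest",
    "MANIFEST_COLUMNS",
]

#: Columns a study manifest CSV must provide, one row per (session, phase).
MANIFEST_COLUMNS = (
    "subject_id",
    "age_years",
    "sex",
    "height_m",
    "mass_kg",
    "day_label",
    "phase",
    "rr_file",
)

VALID_PHASES = ("rest", "stabilisation", "stepping", "recovery")
VALID_DAYS = ("day1", "day7")


@dataclass
class RRSeries:
    """An ordered sequence of R-R (interbeat) intervals in milliseconds.

    ``t_end_s`` is the cumulative end time of each beat in seconds: beat ``i``
    occupies the interval ``(t_end_s[i-1], t_end_s[i]]`` with
    ``t_end_s[0] = intervals_ms[0] / 1000``.  This fixes window assignment
    downstream without ambiguity.
    """

    intervals_ms: np.ndarray
    label: str = ""
    t_end_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        if iv.ndim != 1 or iv.size == 0:
            raise ValueError("RRSeries requires a non-empty 1-D interval sequence")
        if not np.all(iv > 0):
            bad = int(np.flatnonzero(iv <= 0)[0])
            raise ValueError(
                f"all R-R intervals must be strictly positive; "
                f"interval {bad} is {iv[bad]!r} ms"
            )
        self.intervals_ms = iv
        self.t_end_s = np.cumsum(iv) / 1000.0

    @property
    def n_beats(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds (sum of all intervals)."""
        return float(self.t_end_s[-1])

    def slice_time(self, start_s: float, stop_s: float, label: str | None = None) -> "RRSeries":
        """Beats whose end time lies in the half-open window [start_s, stop_s)."""
        mask = (self.t_end_s >= start_s) & (self.t_end_s < stop_s)
        if not mask.any():
            raise ValueError(f"no beats end within [{start_s}, {stop_s}) s")
        return RRSeries(self.intervals_ms[mask], label=label or self.label)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_beats


@dataclass
class SubjectRecord:
    """Anthropometric metadata for one participant."""

    subject_id: str
    age_years: float
    sex: str
    height_m: float
    mass_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.height_m <= 0 or self.mass_kg <= 0:
            raise ValueError("height and mass must be positive")
        if not 3.0 <= self.age_years <= 18.0:
            logger.warning(
                "subject %s age %.1f y outside the paediatric band [3, 18]",
                self.subject_id, self.age_years,
            )

    @property
    def bmi_kg_m2(self) -> float:
        return self.mass_kg / self.height_m**2


@dataclass
class SessionRecord:
    """One measurement occasion: a subject, a day label and its phase streams."""

    subject: SubjectRecord
    day_label: str
    phase_streams: dict[str, RRSeries]
    start_clock_time: str | None = None

    def __post_init__(self) -> None:
        if self.day_label not in VALID_DAYS:
            raise ValueError(f"day_label must be one of {VALID_DAYS}, got {self.day_label!r}")
        unknown = set(self.phase_streams) - set(VALID_PHASES)
        if unknown:
            raise ValueError(f"unknown phase name(s): {sorted(unknown)}")


def _looks_numeric(token: str) -> bool:
    return token[:1].isdigit() or token[:1] in "+-."


def read_rr_text(path: str | os.PathLike, label: str = "") -> RRSeries:
    """Parse a one-interval-per-line R-R text export (milliseconds).

    A single leading header line that does not start with a digit is skipped
    with a logged notice.  Any later non-numeric line is a parse error naming
    the offending line number; zero or negative intervals are rejected.
    """
    intervals: list[float] = []
    first_content_line = True
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip()
            if not token:
                continue
            if first_content_line and not _looks_numeric(token):
                logger.info("%s: skipping header line %d (%r)", path, lineno, token)
                first_content_line = False
                continue
            first_content_line = False
            try:
                value = float(token)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: cannot parse {token!r} as an R-R interval"
                ) from None
            if value <= 0:
                raise ValueError(
                    f"{path}: line {lineno}: non-positive R-R interval {value} ms"
                )
            intervals.append(value)
    if not intervals:
        raise ValueError(f"{path}: file contains no R-R intervals")
    return RRSeries(np.asarray(intervals), label=label or str(path))


def write_rr_text(series: RRSeries, path: str | os.PathLike) -> None:
    """Write one interval per line; integers bare, reals at 1-decimal precision."""
    with open(path, "w", encoding="utf-8") as fh:
        for v in series.intervals_ms:
            if float(v).is_integer():
                fh.write(f"{int(v)}\n")
            else:
                fh.write(f"{v:.1f}\n")


def validate_physiology(series: RRSeries, context: str = "rest") -> list[str]:
    """Plausibility screen; returns warnings, never raises.

    Flags a mean heart rate outside [40, 220] bpm and any single interval
    outside [250, 2500] ms.  ``context`` is echoed into the messages so a
    log reader can tell rest from exercise streams.
    """
    if context not in ("rest", "exercise", "recovery"):
        raise ValueError(f"unknown context {context!r}")
    warnings: list[str] = []
    mean_hr = float(np.mean(60000.0 / series.intervals_ms))
    if not 40.0 <= mean_hr <= 220.0:
        warnings.append(
            f"{context}: mean heart rate {mean_hr:.1f} bpm outside plausible range [40, 220]"
        )
    out = np.flatnonzero((series.intervals_ms < 250.0) | (series.intervals_ms > 2500.0))
    for i in out:
        warnings.append(
            f"{context}: interval {int(i)} = {series.intervals_ms[i]:.1f} ms "
            f"outside plausible range [250, 2500] ms"
        )
    for w in warnings:
        logger.warning("%s (%s)", w, series.label or "unlabelled")
    return warnings


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Load and validate the study manifest CSV (one row per session phase).

    R-R file paths are resolved relative to the manifest's directory.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {sorted(missing)}")
    bad_day = set(df["day_label"]) - set(VALID_DAYS)
    if bad_day:
        raise ValueError(f"manifest day_label values must be in {VALID_DAYS}; got {sorted(bad_day)}")
    bad_phase = set(df["phase"]) - set(VALID_PHASES)
    if bad_phase:
        raise ValueError(f"manifest phase values must be in {VALID_PHASES}; got {sorted(bad_phase)}")
    base = os.path.dirname(os.fspath(path))
    df = df.copy()
    df["rr_file"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["rr_file"]
    ]
    for p in df["rr_file"]:
        if not os.path.exists(p):
            raise FileNotFoundError(f"manifest references missing R-R file: {p}")
    return df
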