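"""End-to-end study analysis: ingest, correct, segment, measure, report.

``run_study`` drives the whole protocol analysis from a manifest CSV to a
bundle of output tables: per-session HRV metrics, test-retest reliability
tables for the 5 min resting phase (time and frequency domain) and for
each 30 s recovery window (time domain only — spectral indices are not
computed on sub-minute windows), beat-correction logs, step-test intensity
summaries, and a run-metadata file recording every parameter the run used
so results are auditable and exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beat_correction import (
    DEFAULT_MAX_FRACTION,
    DEFAULT_THRESHOLD,
    DEFAULT_WINDOW,
    correct_series,
)
from .hrv_freq import MIN_DURATION_S, SpectralConfig, frequency_domain
from .hrv_time import time_domain
from .protocol_segmentation import segment_recovery, step_test_summary
from .reliability_stats import PairedTrials, ReliabilityResult, reliability_result
from .rr_io import read_manifest, read_rr_text

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StudyResult",
    "ValidationError",
    "CohortError",
    "run_study",
    "report_tables",
    "format_estimate_ci",
]

TIME_PARAMS = ["mean_rr_ms", "mean_hr_bpm", "sdnn_ms", "rmssd_ms", "rmssd_ln", "nn50", "pnn50_pct"]
FREQ_PARAMS = [
    "lf_ms2", "hf_ms2", "total_power_ms2", "lf_ln", "hf_ln", "tp_ln",
    "lf_nu", "hf_nu", "lf_hf_ratio", "lf_pct", "hf_pct",
]


class ValidationError(RuntimeError):
    """Bad inputs or configuration (CLI exit code 2)."""


class CohortError(RuntimeError):
    """Fewer than 3 subjects with complete, includable data (CLI exit code 3)."""


@dataclass
class RunConfig:
    manifest_path: str
    out_dir: str
    artifact_threshold: float = DEFAULT_THRESHOLD
    artifact_window: int = DEFAULT_WINDOW
    inclusion_max_fraction: float = DEFAULT_MAX_FRACTION
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    reliability_level: float = 0.90
    seed: int = 0


@dataclass
class StudyResult:
    session_metrics: pd.DataFrame
    reliability: pd.DataFrame
    step_test: pd.DataFrame
    correction_log: pd.DataFrame
    excluded: list[tuple[str, str, str]]  # (subject, day, reason)
    out_dir: str


def _analyse_session(row_group: pd.DataFrame, cfg: RunConfig):
    """Metrics for one (subject, day); returns (metric rows, log rows, step rows) or a reason."""
    subject = row_group["subject_id"].iloc[0]
    day = row_group["day_label"].iloc[0]
    streams = {}
    for _, row in row_group.iterrows():
        streams[row["phase"]] = read_rr_text(row["rr_file"], label=f"{subject}/{day}/{row['phase']}")
    if "rest" not in streams or "recovery" not in streams:
        return None, None, None, "missing rest or recovery stream"

    metric_rows, log_rows, step_rows = [], [], []
    corrected = {}
    for phase, series in streams.items():
        rep = correct_series(
            series,
            rel_threshold=cfg.artifact_threshold,
            window=cfg.artifact_window,
            max_fraction=cfg.inclusion_max_fraction,
        )
        lg = rep.log_frame()
        lg.insert(0, "phase", phase)
        lg.insert(0, "day_label", day)
        lg.insert(0, "subject_id", subject)
        log_rows.append(lg)
        if not rep.included and phase in ("rest", "recovery"):
            return None, None, None, (
                f"{phase}: corrected fraction {rep.corrected_fraction:.1%} exceeds "
                f"{cfg.inclusion_max_fraction:.0%} inclusion limit"
            )
        corrected[phase] = rep.corrected_series

    def emit(window: str, metrics: dict[str, float]) -> None:
        for param, value in metrics.items():
            metric_rows.append({
                "subject_id": subject, "day_label": day, "window": window,
                "parameter": param, "value": value,
            })

    rest = corrected["rest"]
    emit("rest", time_domain(rest).as_dict())
    if rest.duration_s >= MIN_DURATION_S:
        emit("rest", frequency_domain(rest, cfg.spectral).as_dict())
    else:
        logger.info("%s/%s: rest stream %.0f s — frequency domain skipped",
                    subject, day, rest.duration_s)

    for w, win in enumerate(segment_recovery(corrected["recovery"])):
        emit(f"recovery_{30*w}_{30*(w+1)}", time_domain(win).as_dict())

    if "stepping" in corrected:
        age = float(row_group["age_years"].iloc[0])
        st = step_test_summary(corrected["stepping"], age)
        step_rows.append({
            "subject_id": subject, "day_label": day,
            "age_predicted_mhr_bpm": st.age_predicted_mhr_bpm,
            "mean_exercise_hr_bpm": st.mean_exercise_hr_bpm,
            "pct_mhr": st.pct_mhr,
        })
    return metric_rows, log_rows, step_rows, None


def run_study(config: RunConfig) -> StudyResult:
    """Run the full analysis and write the report bundle to ``config.out_dir``."""
    try:
        manifest = read_manifest(config.manifest_path)
    except (ValueError, FileNotFoundError) as exc:
        raise ValidationError(str(exc)) from exc
    os.makedirs(config.out_dir, exist_ok=True)

    metric_rows: list[dict] = []
    log_frames: list[pd.DataFrame] = []
    step_rows: list[dict] = []
    excluded: list[tuple[str, str, str]] = []
    complete: dict[str, set[str]] = {}

    for (subject, day), grp in manifest.groupby(["subject_id", "day_label"], sort=True):
        mrows, lrows, srows, reason = _analyse_session(grp, config)
        if reason is not None:
            logger.info("excluding %s/%s: %s", subject, day, reason)
            excluded.append((subject, day, reason))
            continue
        metric_rows.extend(mrows)
        log_frames.extend(lrows)
        step_rows.extend(srows)
        complete.setdefault(subject, set()).add(day)

    both_days = sorted(s for s, days in complete.items() if days == {"day1", "day7"})
    for subject, days in sorted(complete.items()):
        if days != {"day1", "day7"}:
            missing = ({"day1", "day7"} - days).pop()
            logger.info("excluding %s from reliability: %s missing", subject, missing)
            excluded.append((subject, missing, "day missing"))
    if len(both_days) < 3:
        raise CohortError(
            f"only {len(both_days)} subject(s) with complete two-day data; need >= 3"
        )

    metrics = pd.DataFrame(metric_rows)
    metrics = metrics[metrics["subject_id"].isin(both_days)]

    rel_rows = []
    for window in sorted(metrics["window"].unique()):
        params = TIME_PARAMS + FREQ_PARAMS if window == "rest" else TIME_PARAMS
        sub = metrics[metrics["window"] == window]
        for param in params:
            block = sub[sub["parameter"] == param].pivot(
                index="subject_id", columns="day_label", values="value"
            ).dropna()
            if len(block) < 4:
                continue
            pairs = PairedTrials(list(block.index), block["day1"].values, block["day7"].values)
            try:
                res = reliability_result(pairs, parameter=param, level=config.reliability_level)
            except ValueError as exc:
                logger.warning("%s/%s: reliability skipped (%s)", window, param, exc)
                continue
            rel_rows.append({
                "window": window, "parameter": param, "n": res.n,
                "tem": res.tem, "tem_ci_lo": res.tem_ci90[0], "tem_ci_hi": res.tem_ci90[1],
                "tem_pct": res.tem_pct,
                "tem_pct_ci_lo": res.tem_pct_ci90[0], "tem_pct_ci_hi": res.tem_pct_ci90[1],
                "pearson_r": res.pearson_r,
                "r_ci_lo": res.r_ci90[0], "r_ci_hi": res.r_ci90[1],
                "cv_class": res.cv_class, "r_class": res.r_class,
            })
    reliability = pd.DataFrame(rel_rows)
    step_test = pd.DataFrame(step_rows)
    log_frames = [lg for lg in log_frames if len(lg)]
    correction_log = (
        pd.concat(log_frames, ignore_index=True) if log_frames
        else pd.DataFrame(columns=["subject_id", "day_label", "phase",
                                   "index", "original_ms", "replacement_ms", "rule"])
    )

    metrics.to_csv(os.path.join(config.out_dir, "session_metrics.csv"), index=False)
    reliability.to_csv(os.path.join(config.out_dir, "reliability.csv"), index=False)
    step_test.to_csv(os.path.join(config.out_dir, "step_test.csv"), index=False)
    correction_log.to_csv(os.path.join(config.out_dir, "correction_log.csv"), index=False)

    metadata = {
        "package_version": __version__,
        "manifest": os.path.abspath(config.manifest_path),
        "n_subjects_complete": len(both_days),
        "excluded": [list(e) for e in excluded],
        "artifact_threshold": config.artifact_threshold,
        "artifact_window": config.artifact_window,
        "inclusion_max_fraction": config.inclusion_max_fraction,
        "spectral": dataclasses.asdict(config.spectral),
        "reliability_level": config.reliability_level,
        "seed": config.seed,
    }
    with open(os.path.join(config.out_dir, "run_metadata.yaml"), "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)

    result = StudyResult(metrics, reliability, step_test, correction_log, excluded, config.out_dir)
    report_tables(result)
    return result


def format_estimate_ci(value: float, lo: float, hi: float) -> str:
    """Render ``1.41 (1.07–2.08)``; an undefined estimate becomes an em dash."""
    if any(isinstance(v, float) and math.isnan(v) for v in (value, lo, hi)):
        return "—"
    return f"{value:.2f} ({lo:.2f}–{hi:.2f})"


def report_tables(result: StudyResult) -> str:
    """Write the reliability tables as Markdown; returns the file path."""
    lines = ["# Test-retest reliability", ""]
    for window in sorted(result.reliability["window"].unique()) if len(result.reliability) else []:
        sub = result.reliability[result.reliability["window"] == window]
        lines += [
            f"## {window}", "",
            "| parameter | TEM (90% CI) | TEM% (90% CI) | r (90% CI) | CV class | r class |",
            "|---|---|---|---|---|---|",
        ]
        for _, row in sub.iterrows():
            lines.append(
                "| {p} | {tem} | {tp} | {r} | {cc} | {rc} |".format(
                    p=row["parameter"],
                    tem=format_estimate_ci(row["tem"], row["tem_ci_lo"], row["tem_ci_hi"]),
                    tp=format_estimate_ci(row["tem_pct"], row["tem_pct_ci_lo"], row["tem_pct_ci_hi"]),
                    r=format_estimate_ci(row["pearson_r"], row["r_ci_lo"], row["r_ci_hi"]),
                    cc=row["cv_class"], rc=row["r_class"],
                )
            )
        lines.append("")
    path = os.path.join(result.out_dir, "reliability_tables.md")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
    return path
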