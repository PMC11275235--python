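"""Synthetic R-R series, sessions and test-retest cohorts with known truth.

The study's recordings are not public, so every pipeline stage is exercised
on generated data whose ground truth is known by construction:

* resting series — a mean R-R level (~700 ms in primary-school children)
  modulated by two sinusoids, one in the LF band (baroreflex-like, default
  0.10 Hz) and one in the HF band (respiratory sinus arrhythmia, default
  0.28 Hz — children breathe faster than adults), plus white noise;
* recovery series — mono-exponential lengthening of R-R from a
  post-exercise level back towards rest, the standard first-order model of
  vagal reactivation kinetics;
* artifact injection — independent per-beat corruption that multiplies
  (``high``) or divides (``low``) the interval, returning the ground-truth
  index set for detector recall tests;
* paired cohorts — subject true values drawn from a normal between-subject
  distribution, plus within-subject error that is either additive normal
  with SD equal to the nominal TEM, or multiplicative log-normal calibrated
  so the nominal percent typical error equals the population value of the
  Hopkins TEM% estimand (see ``_lognormal_sigma``).

All generators take an explicit integer seed; nothing touches global RNG
state.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rr_io import RRSeries

__all__ = [
    "RRGenSpec",
    "SyntheticCohortSpec",
    "generate_rr_series",
    "generate_recovery_series",
    "inject_artifacts",
    "generate_paired_cohort",
    "generate_study",
]


@dataclass(frozen=True)
class RRGenSpec:
    """Parameters of the sinusoidally modulated resting R-R model."""

    mean_rr_ms: float = 700.0
    lf_amp_ms: float = 25.0
    lf_freq_hz: float = 0.10
    hf_amp_ms: float = 35.0
    hf_freq_hz: float = 0.28
    noise_sd_ms: float = 10.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0 or self.duration_s <= 0:
            raise ValueError("mean_rr_ms and duration_s must be positive")
        for f in (self.lf_freq_hz, self.hf_freq_hz):
            if not 0.0 < f < 2.0:
                raise ValueError("modulation frequencies must lie in (0, 2) Hz")
        for a in (self.lf_amp_ms, self.hf_amp_ms):
            if a < 0 or a >= self.mean_rr_ms / 2:
                raise ValueError("amplitudes must be in [0, mean_rr/2)")
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be non-negative")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating parameters of a two-trial test-retest cohort.

    Exactly one within-subject error parameterization must be active:
    ``within_subject_tem`` (additive, in parameter units) or
    ``within_subject_cv_pct`` (multiplicative, percent).  With the additive
    form the implied test-retest correlation is
    between_var / (between_var + tem^2); ``true_r`` may be given INSTEAD of
    ``between_subject_sd`` to parameterize the same model through the
    correlation.
    """

    n_subjects: int = 14
    population_mean: float = 700.0
    between_subject_sd: float | None = 60.0
    within_subject_tem: float | None = None
    within_subject_cv_pct: float | None = None
    true_r: float | None = None
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if (self.within_subject_tem is None) == (self.within_subject_cv_pct is None):
            raise ValueError(
                "exactly one of within_subject_tem / within_subject_cv_pct required"
            )
        if self.within_subject_tem is not None and self.within_subject_tem < 0:
            raise ValueError("within_subject_tem must be non-negative")
        if self.within_subject_cv_pct is not None and not 0 <= self.within_subject_cv_pct < 100:
            raise ValueError("within_subject_cv_pct must lie in [0, 100)")
        if (self.between_subject_sd is None) == (self.true_r is None):
            raise ValueError("exactly one of between_subject_sd / true_r required")
        if self.true_r is not None:
            if not 0.0 < self.true_r < 1.0:
                raise ValueError("true_r must lie in (0, 1)")
            if self.within_subject_tem is None:
                raise ValueError("true_r parameterization requires within_subject_tem")
        if not 0.0 <= self.artifact_rate <= 0.3:
            raise ValueError("artifact_rate must lie in [0, 0.3]")

    def resolved_between_sd(self) -> float:
        if self.between_subject_sd is not None:
            return self.between_subject_sd
        # between_var/(between_var + tem^2) = r  =>  between_var = tem^2 r/(1-r)
        tem = self.within_subject_tem
        return tem * math.sqrt(self.true_r / (1.0 - self.true_r))


def _beat_times_iterative(rr_of_t, duration_s: float, rng, noise_sd_ms: float):
    """Build beats sequentially: each interval evaluated at its start time."""
    t = 0.0
    intervals = []
    while t < duration_s:
        rr = rr_of_t(t)
        if noise_sd_ms > 0:
            rr += rng.normal(0.0, noise_sd_ms)
        rr = max(rr, 100.0)  # guard: never emit a non-physiological short beat
        intervals.append(rr)
        t += rr / 1000.0
    return np.asarray(intervals)


def generate_rr_series(spec: RRGenSpec = RRGenSpec()) -> RRSeries:
    """Resting R-R series with LF and HF sinusoidal modulation plus noise."""
    rng = np.random.default_rng(spec.seed)

    def rr_of_t(t: float) -> float:
        return (
            spec.mean_rr_ms
            + spec.lf_amp_ms * math.sin(2 * math.pi * spec.lf_freq_hz * t)
            + spec.hf_amp_ms * math.sin(2 * math.pi * spec.hf_freq_hz * t)
        )

    iv = _beat_times_iterative(rr_of_t, spec.duration_s, rng, spec.noise_sd_ms)
    return RRSeries(iv, label=f"synthetic-rest(seed={spec.seed})")


def generate_recovery_series(
    start_rr_ms: float,
    end_rr_ms: float,
    tau_s: float,
    duration_s: float = 120.0,
    noise_sd_ms: float = 5.0,
    seed: int = 0,
) -> RRSeries:
    """Post-exercise recovery: RR(t) = end - (end-start) exp(-t/tau) + noise.

    R-R intervals lengthen monotonically (heart rate falls) from the
    exercise level ``start_rr_ms`` towards the recovered level
    ``end_rr_ms`` with time constant ``tau_s``.
    """
    if not start_rr_ms < end_rr_ms:
        raise ValueError("start_rr_ms must be below end_rr_ms (HR falls during recovery)")
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    rng = np.random.default_rng(seed)

    def rr_of_t(t: float) -> float:
        return end_rr_ms - (end_rr_ms - start_rr_ms) * math.exp(-t / tau_s)

    iv = _beat_times_iterative(rr_of_t, duration_s, rng, noise_sd_ms)
    return RRSeries(iv, label=f"synthetic-recovery(seed={seed})")


def inject_artifacts(
    series: RRSeries,
    rate: float,
    magnitude: float = 0.5,
    high_frac: float = 0.5,
    seed: int = 0,
) -> tuple[RRSeries, dict[int, str]]:
    """Corrupt each beat independently with probability ``rate``.

    ``high`` corruption multiplies the interval by (1 + magnitude); ``low``
    divides by it.  Returns the corrupted series and the ground-truth
    index -> tag mapping for detector recall measurement.
    """
    if not 0.0 <= rate <= 0.3:
        raise ValueError("rate must lie in [0, 0.3]")
    if magnitude < 0.3:
        raise ValueError("magnitude must be >= 0.3 (smaller deviations are not artifacts)")
    if not 0.0 <= high_frac <= 1.0:
        raise ValueError("high_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iv = series.intervals_ms.copy()
    truth: dict[int, str] = {}
    hit = rng.random(iv.size) < rate
    kinds = rng.random(iv.size) < high_frac
    for i in np.flatnonzero(hit):
        if kinds[i]:
            iv[i] *= 1.0 + magnitude
            truth[int(i)] = "high"
        else:
            iv[i] /= 1.0 + magnitude
            truth[int(i)] = "low"
    return RRSeries(iv, label=f"{series.label}+artifacts"), truth


def _lognormal_sigma(cv_pct: float, between_sd: float, mean: float) -> float:
    """Log-scale SD making the nominal CV the population TEM% of the cohort.

    The Hopkins estimator TEM% = 100*SD(diff)/(sqrt(2)*grand mean) has
    population value 100*sqrt((1+vb)(e^{s^2}-1)) under the multiplicative
    model, where vb = (between_sd/mean)^2; solving for s makes the
    recovered percent typical error equal the nominal CV for any cohort
    geometry (to first order s ~ ln(1+cv/100), the usual approximation).
    """
    vb = (between_sd / mean) ** 2
    return math.sqrt(math.log1p((cv_pct / 100.0) ** 2 / (1.0 + vb)))


def generate_paired_cohort(spec: SyntheticCohortSpec):
    """Draw a two-trial cohort; returns (PairedTrials, ground-truth dict).

    Subject true values are Normal(population_mean, between_subject_sd^2).
    Additive parameterization adds Normal(0, tem^2) per trial; the
    multiplicative one multiplies by exp(Normal(0, s^2)) with s calibrated
    from the nominal CV (see ``_lognormal_sigma``).
    """
    from .reliability_stats import PairedTrials  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    between_sd = spec.resolved_between_sd()
    mu = rng.normal(spec.population_mean, between_sd, spec.n_subjects)
    if spec.within_subject_tem is not None:
        tem = spec.within_subject_tem
        y1 = mu + rng.normal(0.0, tem, spec.n_subjects)
        y2 = mu + rng.normal(0.0, tem, spec.n_subjects)
        implied_r = between_sd**2 / (between_sd**2 + tem**2) if tem > 0 else 1.0
        truth = {
            "model": "additive",
            "tem": tem,
            "between_subject_sd": between_sd,
            "implied_r": implied_r,
        }
    else:
        cv = spec.within_subject_cv_pct
        s = _lognormal_sigma(cv, between_sd, spec.population_mean)
        y1 = mu * np.exp(rng.normal(0.0, s, spec.n_subjects))
        y2 = mu * np.exp(rng.normal(0.0, s, spec.n_subjects))
        truth = {
            "model": "multiplicative",
            "cv_pct": cv,
            "log_sigma": s,
            "between_subject_sd": between_sd,
        }
    ids = [f"S{j:05d}" for j in range(spec.n_subjects)]
    return PairedTrials(ids, y1, y2), truth


def generate_study(
    out_dir: str | os.PathLike,
    n_subjects: int = 14,
    seed: int = 0,
    artifact_rate: float = 0.02,
) -> str:
    """Emit a complete synthetic study ready for the analysis pipeline.

    Writes per-subject R-R text files for rest, stabilisation, stepping and
    recovery on both days plus a ``manifest.csv``; returns the manifest
    path.  Day-to-day variation enters through small random shifts of each
    subject's mean resting R-R and recovery kinetics.
    """
    from .rr_io import write_rr_text

    os.makedirs(out_dir, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    for j in range(n_subjects):
        subj = f"S{j:03d}"
        age = float(master.uniform(4.0, 9.0))
        sex = "female" if master.random() < 0.5 else "male"
        height = float(master.uniform(1.05, 1.40))
        mass = float(master.uniform(16.0, 35.0))
        base_rr = float(master.normal(700.0, 60.0))
        for day in ("day1", "day7"):
            day_rr = base_rr + float(master.normal(0.0, 12.0))
            sub_seed = int(master.integers(0, 2**31 - 1))
            rest = generate_rr_series(RRGenSpec(
                mean_rr_ms=day_rr, duration_s=300.0, seed=sub_seed,
            ))
            stab = generate_rr_series(RRGenSpec(
                mean_rr_ms=day_rr * 0.92, lf_amp_ms=15.0, hf_amp_ms=20.0,
                duration_s=30.0, seed=sub_seed + 1,
            ))
            step = generate_rr_series(RRGenSpec(
                mean_rr_ms=day_rr * 0.62, lf_amp_ms=8.0, hf_amp_ms=8.0,
                noise_sd_ms=5.0, duration_s=180.0, seed=sub_seed + 2,
            ))
            reco = generate_recovery_series(
                start_rr_ms=day_rr * 0.62, end_rr_ms=day_rr * 0.95,
                tau_s=35.0, duration_s=121.0, seed=sub_seed + 3,
            )
            streams = {"rest": rest, "stabilisation": stab, "stepping": step, "recovery": reco}
            for phase, series in streams.items():
                if artifact_rate > 0 and phase in ("rest", "recovery"):
                    series, _ = inject_artifacts(
                        series, rate=artifact_rate, magnitude=0.5, seed=sub_seed + 7,
                    )
                fname = f"{subj}_{day}_{phase}.txt"
                write_rr_text(series, os.path.join(out_dir, fname))
                rows.append({
                    "subject_id": subj, "age_years": round(age, 1), "sex": sex,
                    "height_m": round(height, 2), "mass_kg": round(mass, 1),
                    "day_label": day, "phase": phase, "rr_file": fname,
                })
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
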