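import math

import numpy as np
import pytest

from hrvrel import (
    RRGenSpec,
    SyntheticCohortSpec,
    frequency_domain,
    generate_paired_cohort,
    generate_recovery_series,
    generate_rr_series,
    inject_artifacts,
    pearson_with_ci,
    segment_recovery,
    time_domain,
    typical_error,
)


class TestGenerateRRSeries:
    def test_no_modulation_is_constant_at_mean(self):
        s = generate_rr_series(RRGenSpec(lf_amp_ms=0, hf_amp_ms=0, noise_sd_ms=0, duration_s=60))
        np.testing.assert_allclose(s.intervals_ms, 700.0)

    def test_seed_determinism(self):
        spec = RRGenSpec(seed=123)
        a, b = generate_rr_series(spec), generate_rr_series(spec)
        np.testing.assert_array_equal(a.intervals_ms, b.intervals_ms)
        c = generate_rr_series(RRGenSpec(seed=124))
        assert not np.array_equal(a.intervals_ms, c.intervals_ms)

    def test_hf_only_modulation_lands_in_hf_band(self):
        s = generate_rr_series(RRGenSpec(lf_amp_ms=0, hf_amp_ms=40, noise_sd_ms=2, seed=5))
        assert frequency_domain(s).hf_nu > 90

    def test_duration_reached(self):
        s = generate_rr_series(RRGenSpec(duration_s=300, seed=1))
        assert s.duration_s >= 300.0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            RRGenSpec(lf_amp_ms=400.0)  # amplitude >= mean/2
        with pytest.raises(ValueError):
            RRGenSpec(hf_freq_hz=2.5)


class TestGenerateRecovery:
    def test_closed_form_without_noise(self):
        tau, start, end = 30.0, 480.0, 660.0
        s = generate_recovery_series(start, end, tau, duration_s=200.0, noise_sd_ms=0.0)
        # at t = tau the deterministic model gives end - (end-start)/e
        t_start = np.concatenate([[0.0], s.t_end_s[:-1]])
        idx = np.argmin(np.abs(t_start - tau))
        expected = end - (end - start) * math.exp(-t_start[idx] / tau)
        assert s.intervals_ms[idx] == pytest.approx(expected, rel=1e-12)
        # approaches the recovered level late in the recording
        assert s.intervals_ms[-1] == pytest.approx(end, rel=0.01)

    def test_monotone_recovery_across_windows(self):
        s = generate_recovery_series(480.0, 660.0, 35.0, noise_sd_ms=0.0)
        windows = segment_recovery(s)
        means = [time_domain(w).mean_rr_ms for w in windows]
        assert means == sorted(means)
        assert means[0] < means[-1]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_recovery_series(700.0, 600.0, 30.0)
        with pytest.raises(ValueError):
            generate_recovery_series(480.0, 660.0, -1.0)


class TestInjectArtifacts:
    def test_rate_zero_is_identity(self, clean_series):
        out, truth = inject_artifacts(clean_series, rate=0.0)
        np.testing.assert_array_equal(out.intervals_ms, clean_series.intervals_ms)
        assert truth == {}

    def test_binomial_expectation(self):
        s = generate_rr_series(RRGenSpec(duration_s=700, seed=8))  # ~1000 beats
        _, truth = inject_artifacts(s, rate=0.05, seed=2)
        assert 0.05 * s.n_beats == pytest.approx(len(truth), abs=3 * math.sqrt(0.05 * s.n_beats))

    def test_truth_tags_match_corruption_direction(self, clean_series):
        out, truth = inject_artifacts(clean_series, rate=0.1, magnitude=0.5, seed=4)
        for i, tag in truth.items():
            ratio = out.intervals_ms[i] / clean_series.intervals_ms[i]
            assert ratio == pytest.approx(1.5 if tag == "high" else 1 / 1.5)


class TestPairedCohort:
    def test_zero_tem_gives_identical_trials(self):
        pairs, truth = generate_paired_cohort(SyntheticCohortSpec(
            n_subjects=50, within_subject_tem=0.0, seed=1))
        np.testing.assert_array_equal(pairs.trial1, pairs.trial2)
        assert typical_error(pairs)[0] == 0.0

    def test_additive_tem_recovered_at_large_n(self):
        pairs, _ = generate_paired_cohort(SyntheticCohortSpec(
            n_subjects=100_000, within_subject_tem=5.0, seed=7))
        assert typical_error(pairs)[0] == pytest.approx(5.0, rel=0.01)

    def test_multiplicative_cv_recovered_at_large_n(self):
        pairs, _ = generate_paired_cohort(SyntheticCohortSpec(
            n_subjects=100_000, population_mean=4.0, between_subject_sd=0.5,
            within_subject_cv_pct=5.2, seed=7))
        assert typical_error(pairs)[1] == pytest.approx(5.2, abs=0.2)

    def test_true_r_parameterization_recovered(self):
        pairs, truth = generate_paired_cohort(SyntheticCohortSpec(
            n_subjects=100_000, between_subject_sd=None, true_r=0.86,
            within_subject_tem=1.41, population_mean=705.0, seed=3))
        r, _ = pearson_with_ci(pairs)
        assert r == pytest.approx(0.86, abs=0.01)

    def test_exactly_one_parameterization(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(within_subject_tem=1.0, within_subject_cv_pct=5.0)
        with pytest.raises(ValueError):
            SyntheticCohortSpec()
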