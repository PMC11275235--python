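import numpy as np
import pytest

from hrvrel import (
    RRSeries,
    correct_artifacts,
    correct_series,
    flag_artifacts,
    inject_artifacts,
)


class TestFlagArtifacts:
    def test_long_interval_flagged_high(self):
        flags = flag_artifacts(RRSeries([800, 810, 1200, 805]))
        assert flags == {2: "high"}

    def test_short_interval_flagged_low(self):
        flags = flag_artifacts(RRSeries([800, 400, 810]))
        assert flags == {1: "low"}

    def test_constant_series_unflagged(self):
        assert flag_artifacts(RRSeries([700.0] * 50)) == {}

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            flag_artifacts(RRSeries([800, 810]))

    @pytest.mark.parametrize("kw", [{"rel_threshold": 0}, {"window": 4}, {"window": 1}])
    def test_parameter_validation(self, kw):
        with pytest.raises(ValueError):
            flag_artifacts(RRSeries([800] * 10), **kw)


class TestCorrectArtifacts:
    def test_high_replaced_by_neighbour_mean_and_inclusion(self):
        s = RRSeries([800, 810, 1200, 805])
        rep = correct_artifacts(s, {2: "high"})
        np.testing.assert_allclose(rep.corrected_series.intervals_ms, [800, 810, 807.5, 805])
        assert rep.corrected_fraction == pytest.approx(0.25)
        assert rep.included is False  # 1/4 beats exceeds the 20 % criterion
        assert rep.per_beat_log == [(2, 1200.0, 807.5, "high")]

    def test_low_replaced_by_previous_interval(self):
        rep = correct_artifacts(RRSeries([800, 400, 810]), {1: "low"})
        np.testing.assert_allclose(rep.corrected_series.intervals_ms, [800, 800, 810])
        assert rep.corrected_fraction == pytest.approx(1 / 3)

    def test_no_flags_is_identity_and_included(self, clean_series):
        rep = correct_artifacts(clean_series, {})
        np.testing.assert_array_equal(
            rep.corrected_series.intervals_ms, clean_series.intervals_ms
        )
        assert rep.corrected_fraction == 0.0 and rep.included is True

    def test_edge_flags_use_available_neighbour(self):
        rep = correct_artifacts(RRSeries([1500, 800, 810, 790]), {0: "high"})
        assert rep.corrected_series.intervals_ms[0] == 800.0
        rep = correct_artifacts(RRSeries([400, 800, 810]), {0: "low"})
        assert rep.corrected_series.intervals_ms[0] == 800.0
        rep = correct_artifacts(RRSeries([800, 810, 1500]), {2: "high"})
        assert rep.corrected_series.intervals_ms[2] == 810.0

    def test_single_pass_uses_original_neighbours(self):
        # adjacent flags must not see each other's replacements
        s = RRSeries([800, 1300, 1290, 810])
        rep = correct_artifacts(s, {1: "high", 2: "high"})
        np.testing.assert_allclose(
            rep.corrected_series.intervals_ms, [800, (800 + 1290) / 2, (1300 + 810) / 2, 810]
        )

    def test_length_always_preserved(self, clean_series):
        corrupted, _ = inject_artifacts(clean_series, rate=0.1, seed=3)
        rep = correct_series(corrupted)
        assert rep.corrected_series.n_beats == corrupted.n_beats


class TestPipelineProperties:
    def test_idempotence_on_corrected_output(self, clean_series):
        # idempotence holds when artifacts are isolated: a replacement built
        # from a corrupted original neighbour can itself remain deviant
        corrupted, truth = inject_artifacts(clean_series, rate=0.02, magnitude=0.6, seed=11)
        idx = sorted(truth)
        assert all(b - a >= 3 for a, b in zip(idx, idx[1:]))
        once = correct_series(corrupted)
        again = correct_series(once.corrected_series)
        np.testing.assert_array_equal(
            again.corrected_series.intervals_ms, once.corrected_series.intervals_ms
        )
        assert again.corrected_fraction == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recall_of_injected_artifacts(self, clean_series, seed):
        corrupted, truth = inject_artifacts(clean_series, rate=0.05, magnitude=0.6, seed=seed)
        flags = flag_artifacts(corrupted)
        recall = len(set(truth) & set(flags)) / len(truth)
        assert recall >= 0.9

    def test_corrected_fraction_monotone_in_artifact_count(self, clean_series):
        fractions = []
        for rate in (0.0, 0.03, 0.08, 0.15):
            corrupted, _ = inject_artifacts(clean_series, rate=rate, magnitude=0.6, seed=5)
            fractions.append(correct_series(corrupted).corrected_fraction)
        assert fractions == sorted(fractions)
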