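import math

import numpy as np
import pytest

from hrvrel import (
    PairedTrials,
    classify_cv,
    classify_r,
    paired_ttest,
    pearson_with_ci,
    reliability_result,
    sample_size_pearson,
    tem_confidence_interval,
    typical_error,
)


def make_pairs(t1, t2):
    return PairedTrials([f"s{i}" for i in range(len(t1))], t1, t2)


class TestTypicalError:
    def test_hand_worked_example(self):
        # d = (2, -2, 3): SD sqrt(7); TEM sqrt(7)/sqrt(2); grand mean 110.5
        tem, tem_pct = typical_error(make_pairs([100, 110, 120], [102, 108, 123]))
        assert tem == pytest.approx(math.sqrt(7 / 2), rel=1e-12)
        assert tem_pct == pytest.approx(100 * math.sqrt(3.5) / 110.5, rel=1e-12)

    def test_identical_trials_zero_error(self):
        tem, _ = typical_error(make_pairs([90, 100, 110], [90, 100, 110]))
        assert tem == 0.0

    def test_scale_property(self):
        t1, t2 = [100, 110, 120], [102, 108, 123]
        tem, tem_pct = typical_error(make_pairs(t1, t2))
        tem10, tem_pct10 = typical_error(make_pairs([10 * x for x in t1], [10 * x for x in t2]))
        assert tem10 == pytest.approx(10 * tem)
        assert tem_pct10 == pytest.approx(tem_pct)

    def test_nonpositive_grand_mean_flags_pct(self):
        tem, tem_pct = typical_error(make_pairs([-1.0, -2.0, -3.0], [-1.5, -2.5, -2.0]))
        assert tem > 0 and math.isnan(tem_pct)

    def test_listwise_deletion(self):
        pairs = make_pairs([100, 110, np.nan, 120], [102, 108, 115, 123])
        assert pairs.n == 3

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            typical_error(make_pairs([1, 2], [1, 2]))


class TestTemCI:
    def test_chi_square_interval_n14(self):
        lo, hi = tem_confidence_interval(0.24, 14)
        assert (round(lo, 2), round(hi, 2)) == (0.18, 0.36)

    def test_zero_tem_degenerate(self):
        assert tem_confidence_interval(0.0, 10) == (0.0, 0.0)

    def test_ratio_depends_only_on_n(self):
        for tem in (0.1, 3.7, 120.0):
            lo, hi = tem_confidence_interval(tem, 14)
            assert hi / lo == pytest.approx(
                tem_confidence_interval(1.0, 14)[1] / tem_confidence_interval(1.0, 14)[0]
            )


class TestPearsonCI:
    @pytest.mark.parametrize("r,expected", [(0.86, (0.66, 0.95)), (0.78, (0.50, 0.91))])
    def test_fisher_ci_rounds_to_published_bounds(self, r, expected):
        # build an n=14 dataset with exactly this correlation, then check bounds
        z = math.atanh(r)
        half = 1.6448536269514722 / math.sqrt(11)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_ci_from_constructed_cohort(self, rng):
        # empirical r of a generated n=14 cohort is re-wrapped exactly
        x = rng.normal(0, 1, 14)
        y = 0.8 * x + rng.normal(0, 0.5, 14)
        r, (lo, hi) = pearson_with_ci(make_pairs(x, y))
        assert lo < r < hi
        assert lo == pytest.approx(math.tanh(math.atanh(r) - 1.6448536 / math.sqrt(11)), abs=1e-6)

    def test_perfect_correlation_capped(self):
        r, ci = pearson_with_ci(make_pairs([1, 2, 3, 4], [2, 4, 6, 8]))
        assert r == 1.0 and ci == (1.0, 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_with_ci(make_pairs([5, 5, 5, 5], [1, 2, 3, 4]))


class TestClassification:
    @pytest.mark.parametrize("cv,label", [
        (4.99, "low"), (5.0, "moderate"), (5.2, "moderate"), (8.7, "moderate"),
        (10.0, "moderate"), (10.01, "high"), (10.7, "high"),
    ])
    def test_cv_bins(self, cv, label):
        assert classify_cv(cv) == label

    @pytest.mark.parametrize("r,label", [
        (0.49, "poor"), (0.5, "moderate"), (0.749, "moderate"), (0.75, "good"),
        (0.86, "good"), (0.899, "good"), (0.9, "excellent"), (0.99, "excellent"),
    ])
    def test_r_bins(self, r, label):
        assert classify_r(r) == label


class TestPairedTTest:
    def test_symmetric_differences_give_t_zero(self):
        t, df, p = paired_ttest(make_pairs([0, 0, 0, 0], [1, -1, 2, -2]))
        assert t == pytest.approx(0.0) and df == 3 and p == pytest.approx(1.0)

    def test_hand_worked_t(self):
        t, df, p = paired_ttest(make_pairs([100, 110, 120], [102, 108, 123]))
        assert t == pytest.approx(1 / (math.sqrt(7) / math.sqrt(3)), rel=1e-9)
        assert df == 2

    def test_constant_shift_is_error(self):
        with pytest.raises(ValueError):
            paired_ttest(make_pairs([1, 2, 3], [6, 7, 8]))

    def test_identical_trials_report_p_one(self):
        t, _, p = paired_ttest(make_pairs([1, 2, 3], [1, 2, 3]))
        assert t == 0.0 and p == 1.0

    def test_matches_scipy(self, rng):
        from scipy import stats
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 1, 20)
        t, df, p = paired_ttest(make_pairs(x, y))
        ref = stats.ttest_rel(y, x)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestSampleSize:
    def test_standard_formula_values(self):
        assert sample_size_pearson(0.70, 0.05, 0.90, sides=2) == 17
        assert sample_size_pearson(0.70, 0.05, 0.90, sides=1) == 15

    def test_limit_and_domain(self):
        assert sample_size_pearson(0.999999) == 4
        with pytest.raises(ValueError):
            sample_size_pearson(1.0)
        with pytest.raises(ValueError):
            sample_size_pearson(0.0)


class TestResultAssembly:
    def test_full_block_consistency(self, rng):
        x = rng.normal(100, 15, 14)
        y = x + rng.normal(0, 5, 14)
        res = reliability_result(make_pairs(x, y), parameter="demo")
        assert res.tem_ci90[0] <= res.tem <= res.tem_ci90[1]
        assert res.tem_pct_ci90[0] <= res.tem_pct <= res.tem_pct_ci90[1]
        assert res.r_ci90[0] <= res.pearson_r <= res.r_ci90[1]
        assert res.cv_class == classify_cv(res.tem_pct)
        assert res.r_class == classify_r(res.pearson_r)
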