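"""Unit and property tests for the trading randomization test."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ctenotrade import (
    AbsoluteDifferenceTotal,
    InsufficientDataError,
    PairedSpawnReplicate,
    Tail,
    Treatment,
    UndefinedSplitError,
    absolute_difference_total,
    analytic_p_value,
    build_null_distribution,
    compare_treatment_differences,
    filter_double_zero,
    filter_low_total,
    irwin_hall_cdf,
    mc_p_value,
    proportion_split,
    sensitivity_rerun,
    simulate_null_total,
    trading_test,
)
from conftest import make_pairs


class TestProportionSplit:
    @pytest.mark.parametrize(
        "a, b, p_a, abs_diff",
        [
            (100, 100, 0.5, 0.0),
            (437, 0, 1.0, 1.0),
            (300, 100, 0.75, 0.5),
        ],
    )
    def test_examples(self, a, b, p_a, abs_diff):
        s = proportion_split(a, b)
        assert s.p_a == pytest.approx(p_a)
        assert s.abs_diff == pytest.approx(abs_diff)

    def test_zero_total_refused(self):
        with pytest.raises(UndefinedSplitError):
            proportion_split(0, 0)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_invariants(self, a, b):
        if a + b == 0:
            return
        s = proportion_split(a, b)
        assert abs(s.p_a + s.p_b - 1.0) <= 1e-12
        assert s.abs_diff == pytest.approx(abs(s.p_a - s.p_b))
        swapped = proportion_split(b, a)
        assert swapped.abs_diff == pytest.approx(s.abs_diff)


class TestFilters:
    def test_double_zero_exclusion_bookkeeping(self):
        counts = [(10, 20)] * 26 + [(0, 0)] * 3
        reps = make_pairs(counts)
        kept = filter_double_zero(reps)
        assert len(kept) == 26
        assert len(reps) == 29  # input untouched
        assert kept == [r for r in reps if r.total > 0]  # order preserved

    def test_double_zero_identity_cases(self):
        assert filter_double_zero([]) == []
        reps = make_pairs([(1, 0), (5, 5)])
        assert filter_double_zero(reps) == reps

    @pytest.mark.parametrize(
        "total, threshold, kept",
        [(25, 25, False), (26, 25, True), (1, 0, True)],
    )
    def test_low_total_boundary(self, total, threshold, kept):
        reps = make_pairs([(total, 0)])
        assert bool(filter_low_total(reps, threshold)) is kept

    @given(
        st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100)), max_size=30),
        st.integers(0, 50),
    )
    def test_low_total_retains_order_and_bound(self, counts, threshold):
        reps = make_pairs(counts)
        kept = filter_low_total(reps, threshold)
        assert all(r.total > threshold for r in kept)
        assert kept == [r for r in reps if r.total > threshold]


class TestAbsoluteDifferenceTotal:
    def test_hand_sum(self):
        reps = make_pairs([(300, 100), (100, 100), (0, 50)])
        res = absolute_difference_total(reps)
        assert res.value == pytest.approx(1.5)  # 0.5 + 0 + 1.0
        assert res.n_replicates == 3

    def test_extremes(self):
        assert absolute_difference_total(make_pairs([(437, 0)])).value == 1.0
        reps = make_pairs([(7, 7)] * 26)
        assert absolute_difference_total(reps).value == pytest.approx(0.0)

    def test_zero_total_replicate_rejected(self):
        with pytest.raises(UndefinedSplitError):
            absolute_difference_total(make_pairs([(1, 1), (0, 0)]))

    def test_unpaired_replicate_rejected(self):
        solo = PairedSpawnReplicate("S1", Treatment.SOLITARY, 100, None)
        with pytest.raises(UndefinedSplitError):
            absolute_difference_total([solo])

    @given(
        st.lists(
            st.tuples(st.integers(0, 1000), st.integers(0, 1000)).filter(
                lambda ab: sum(ab) > 0
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_bounds_and_side_symmetry(self, counts):
        reps = make_pairs(counts)
        res = absolute_difference_total(reps)
        assert 0.0 <= res.value <= res.n_replicates
        swapped = absolute_difference_total([r.swapped() for r in reps])
        assert swapped.value == pytest.approx(res.value)
        one_sided = all(0 in pair for pair in counts)
        assert (res.value == pytest.approx(res.n_replicates)) == one_sided


class TestNullDistribution:
    def test_single_total_range_and_empty(self, rng):
        assert simulate_null_total(0, rng) == 0.0
        t = simulate_null_total(26, rng)
        assert 0.0 <= t <= 26.0

    def test_determinism(self):
        a = build_null_distribution(26, 2000, seed=42)
        b = build_null_distribution(26, 2000, seed=42)
        assert np.array_equal(a.totals, b.totals)

    def test_moments_match_uniform_sum(self):
        null = build_null_distribution(26, 10_000, seed=3)
        assert null.totals.mean() == pytest.approx(13.0, abs=0.05)
        assert null.totals.std() == pytest.approx(np.sqrt(26 / 12), abs=0.05)

    def test_single_replicate_null_is_uniform(self):
        null = build_null_distribution(1, 10_000, seed=5)
        assert stats.kstest(null.totals, stats.uniform.cdf).pvalue > 0.01

    def test_distribution_equals_direct_uniform_sums(self):
        null = build_null_distribution(26, 10_000, seed=9)
        direct = np.random.default_rng(1009).random((10_000, 26)).sum(axis=1)
        assert stats.ks_2samp(null.totals, direct).pvalue > 0.01

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            build_null_distribution(26, 0, seed=1)


class TestIrwinHall:
    def test_symmetry_and_support(self):
        assert irwin_hall_cdf(13, 26) == pytest.approx(0.5)
        assert irwin_hall_cdf(0, 26) == 0.0
        assert irwin_hall_cdf(26, 26) == 1.0
        assert irwin_hall_cdf(-1, 5) == 0.0
        assert irwin_hall_cdf(6, 5) == 1.0

    def test_exact_rational_tail_values(self):
        # frozen from the exact big-rational alternating sum
        assert irwin_hall_cdf(Fraction(38, 5), 26) == pytest.approx(
            8.819279318229868e-05, rel=1e-9
        )
        assert 1.0 - irwin_hall_cdf(Fraction(79, 5), 26) == pytest.approx(
            0.02841974940405323, rel=1e-9
        )

    @pytest.mark.parametrize("n", [1, 2, 5, 26])
    def test_against_scipy_oracle(self, n):
        xs = np.linspace(0.05, n - 0.05, 23)
        ours = np.array([irwin_hall_cdf(x, n) for x in xs])
        ref = stats.irwinhall(n).cdf(xs)
        assert np.allclose(ours, ref, rtol=1e-9, atol=1e-12)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            irwin_hall_cdf(1.0, 0)


class TestPValues:
    def test_reflection_identity(self):
        for x in [2.3, 7.6, 10.2, 13.0, 15.8, 24.1]:
            up = analytic_p_value(AbsoluteDifferenceTotal(x, 26), Tail.UPPER)
            lo = analytic_p_value(AbsoluteDifferenceTotal(26 - x, 26), Tail.LOWER)
            assert up == pytest.approx(lo, rel=1e-9, abs=1e-15)

    def test_center_and_extremes(self):
        assert analytic_p_value(
            AbsoluteDifferenceTotal(13.0, 26), Tail.LOWER
        ) == pytest.approx(0.5)
        null = build_null_distribution(26, 1000, seed=0)
        res = mc_p_value(AbsoluteDifferenceTotal(0.0, 26), null, Tail.LOWER)
        assert res.p_mc == 0.0
        assert res.exceed_count == 0

    def test_mc_matches_analytic_within_binomial_error(self):
        null = build_null_distribution(26, 10_000, seed=17)
        for x in [10.0, 11.5, 13.0, 14.5, 16.0]:
            obs = AbsoluteDifferenceTotal(x, 26)
            for tail in (Tail.UPPER, Tail.LOWER):
                res = mc_p_value(obs, null, tail)
                p = res.p_analytic
                bound = 4 * np.sqrt(p * (1 - p) / null.n_sims) + 1e-9
                assert abs(res.p_mc - p) <= bound

    def test_tie_correction_never_zero(self):
        null = build_null_distribution(26, 1000, seed=0)
        res = mc_p_value(
            AbsoluteDifferenceTotal(0.0, 26), null, Tail.LOWER, tie_correction=True
        )
        assert res.p_mc == pytest.approx(1 / 1001)

    def test_replicate_count_mismatch(self):
        null = build_null_distribution(24, 100, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            mc_p_value(AbsoluteDifferenceTotal(10.0, 26), null, Tail.UPPER)


class TestTradingTest:
    def test_auto_tail_selection(self):
        high = make_pairs([(100, 0)] * 20)
        res = trading_test(high, n_sims=500, seed=1)
        assert res.tail is Tail.UPPER
        low = make_pairs([(50, 50)] * 20)
        res = trading_test(low, n_sims=500, seed=1)
        assert res.tail is Tail.LOWER

    def test_all_filtered_out(self):
        with pytest.raises(InsufficientDataError):
            trading_test(make_pairs([(0, 0)] * 3), n_sims=100, seed=0)

    def test_filters_recorded(self):
        reps = make_pairs([(100, 5)] * 10 + [(0, 0)] * 2 + [(3, 4)])
        res = trading_test(reps, tail=Tail.UPPER, n_sims=200, seed=0,
                           low_egg_threshold=25)
        assert res.observed.n_replicates == 10
        assert any("double_zero_excluded=2" in f for f in res.filters_applied)
        assert any("low_total_excluded=1" in f for f in res.filters_applied)


class TestSensitivityRerun:
    def test_null_rebuilt_with_reduced_count(self):
        reps = make_pairs([(300, 10)] * 24 + [(12, 8), (9, 2)])
        res = sensitivity_rerun(reps, threshold=25, n_sims=500, seed=3)
        assert res.observed.n_replicates == 24

    def test_identity_when_nothing_below_threshold(self):
        reps = make_pairs([(300, 10)] * 12)
        full = trading_test(reps, tail=Tail.UPPER, n_sims=500, seed=3)
        sens = sensitivity_rerun(reps, threshold=25, n_sims=500, seed=3)
        assert sens.observed == full.observed
        assert sens.p_mc == full.p_mc

    def test_total_drops_by_removed_contributions(self):
        kept = [(300, 10)] * 20
        removed = [(12, 8), (9, 2)]
        full = absolute_difference_total(make_pairs(kept + removed))
        sens = sensitivity_rerun(
            make_pairs(kept + removed), threshold=25, n_sims=200, seed=0
        )
        removed_contrib = sum(
            proportion_split(a, b).abs_diff for a, b in removed
        )
        assert sens.observed.value == pytest.approx(full.value - removed_contrib)


class TestTwoSampleComparison:
    def test_identical_groups(self):
        res = compare_treatment_differences([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        res = compare_treatment_differences([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        # t = -0.6 / sqrt(0.01 * (1/3 + 1/3)) = -0.6 * sqrt(150)
        assert res.t_statistic == pytest.approx(-0.6 * np.sqrt(150), rel=1e-9)
        assert res.degrees_freedom == 4
        assert res.variant == "pooled"

    def test_welch_variant_recorded(self):
        res = compare_treatment_differences(
            [0.1, 0.2, 0.3, 0.35], [0.7, 0.9], variant="welch"
        )
        assert res.variant == "welch"
        assert res.degrees_freedom < 4  # Welch df below pooled df here

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_treatment_differences([0.5], [0.1, 0.2])
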