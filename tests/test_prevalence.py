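"""Age-structured prevalence chain: onset, incidence, survival, totals."""

import numpy as np
import pytest

from redprev.prevalence import (
    BIN_WIDTH,
    Dm1SurvivalRules,
    OnsetDistribution,
    PenetranceCurve,
    PopulationPyramid,
    aggregate_bins,
    apply_dm1_survival,
    apply_survival,
    dm1_survival_fraction,
    expected_new_cases,
    normalize_onset,
    reported_prevalence_c9als,
    reported_prevalence_c9ftd,
    reported_prevalence_hd40,
    total_prevalence,
)
from redprev.simulate import simulate_epi_inputs

STARTS = np.arange(0, 95, 5)


def survival_oracle(m, n_years):
    """Per-year brute force: spread each bin's incidence uniformly over its
    5 years, cumulate over the trailing n years, read at each bin's last year."""
    inc = np.repeat(np.asarray(m, dtype=float) / BIN_WIDTH, BIN_WIDTH)
    prev = np.zeros(len(m))
    for k in range(len(m)):
        y_end = k * BIN_WIDTH + BIN_WIDTH - 1
        lo = max(0, y_end - n_years + 1)
        prev[k] = inc[lo : y_end + 1].sum()
    return prev


class TestOnsetNormalization:
    def test_counts_become_proportions(self):
        dist = OnsetDistribution([0, 5, 10], [10, 30, 60])
        out = normalize_onset(dist)
        assert np.allclose(out.counts, [0.1, 0.3, 0.6])

    def test_degenerate_single_bin(self):
        out = normalize_onset(OnsetDistribution([40], [7]))
        assert out.counts.tolist() == [1.0]

    def test_random_distributions_normalize_to_one(self, rng):
        for _ in range(200):
            counts = rng.random(len(STARTS)) * 100
            out = normalize_onset(OnsetDistribution(STARTS, counts))
            assert abs(out.counts.sum() - 1.0) < 1e-12

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_onset(OnsetDistribution([0, 5], [0, 0]))


class TestExpectedNewCases:
    def _inputs(self):
        pyramid = PopulationPyramid([0, 5, 10], [100_000, 100_000, 100_000])
        onset = OnsetDistribution([0, 5, 10], [0, 1, 0])
        return pyramid, onset

    def test_zero_frequency_gives_zero_cases(self):
        pyramid, onset = self._inputs()
        assert np.all(expected_new_cases(0.0, pyramid, onset) == 0)

    def test_direct_arithmetic_single_bin(self):
        pyramid, onset = self._inputs()
        m = expected_new_cases(1 / 1000, pyramid, onset)
        assert m.tolist() == [0.0, 100.0, 0.0]

    def test_constant_penetrance_scales_linearly(self, rng):
        pyramid = PopulationPyramid(STARTS, rng.integers(1000, 10_000, len(STARTS)))
        onset = OnsetDistribution(STARTS, rng.random(len(STARTS)) + 0.01)
        full = expected_new_cases(1e-3, pyramid, onset)
        half = expected_new_cases(1e-3, pyramid, onset, PenetranceCurve.constant(0.5))
        assert np.allclose(half, 0.5 * full)

    def test_misaligned_bins_name_first_mismatch(self):
        pyramid = PopulationPyramid([0, 5, 10], [1, 1, 1])
        onset = OnsetDistribution([5, 10, 15], [1, 1, 1])
        with pytest.raises(ValueError, match="index 0"):
            expected_new_cases(1e-3, pyramid, onset)


class TestSurvivalWindow:
    def test_window_of_one_bin_is_identity(self, rng):
        m = rng.random(10)
        assert np.allclose(apply_survival(m, BIN_WIDTH), m)

    def test_lifelong_survival_is_cumulative(self):
        assert apply_survival(np.array([1.0, 1.0, 1.0]), None).tolist() == [1, 2, 3]

    def test_fifteen_years_is_three_bin_trailing_sum(self, rng):
        m = rng.random(12)
        expected = m + np.concatenate([[0], m[:-1]]) + np.concatenate([[0, 0], m[:-2]])
        assert np.allclose(apply_survival(m, 15), expected)

    @pytest.mark.parametrize("n_years", [3, 10, 15, 7, 13])
    def test_matches_per_year_oracle(self, rng, n_years):
        for _ in range(50):
            m = rng.random(len(STARTS)) * 10
            assert np.allclose(apply_survival(m, n_years), survival_oracle(m, n_years))

    def test_shorter_survival_never_increases_prevalence(self, rng):
        for _ in range(50):
            m = rng.random(len(STARTS))
            for n1, n2 in [(3, 10), (10, 15), (15, 40)]:
                assert np.all(apply_survival(m, n1) <= apply_survival(m, n2) + 1e-12)


class TestDm1Survival:
    def test_eighty_percent_at_ten_years_post_onset(self):
        assert dm1_survival_fraction(5, 15) == pytest.approx(0.80)
        assert dm1_survival_fraction(20, 30) == pytest.approx(0.80)

    def test_full_survival_before_ten_years(self):
        assert dm1_survival_fraction(5, 14.9) == 1.0

    def test_extinction_at_mean_death_ages(self):
        assert dm1_survival_fraction(5, 45) == 0.0  # childhood onset
        assert dm1_survival_fraction(20, 52) == 0.0  # early-adult onset
        assert dm1_survival_fraction(5, 44) > 0.0

    def test_late_onset_has_normal_life_expectancy(self):
        assert dm1_survival_fraction(40, 90) == 1.0

    def test_all_late_onset_cohort_equals_lifelong_survival(self, rng):
        m = np.zeros(len(STARTS))
        m[7:] = rng.random(len(STARTS) - 7)  # onset at 35 and later only
        assert np.allclose(
            apply_dm1_survival(m, STARTS), apply_survival(m, None)
        )

    def test_declines_linearly_between_ten_years_and_death(self):
        # childhood onset at 5: 80% at age 15, linear to 0 at 45
        ages = np.arange(15, 46)
        fracs = [dm1_survival_fraction(5, a) for a in ages]
        assert np.allclose(fracs, 0.8 * (45 - ages) / 30)


class TestTotals:
    def test_single_bin_rate_arithmetic(self):
        pyramid = PopulationPyramid([50], [1_000_000])
        total, rate = total_prevalence(np.array([18.0]), pyramid)
        assert total == 18.0
        assert rate == pytest.approx(1.8)

    def test_rate_invariant_under_joint_scaling(self, rng):
        counts = rng.integers(1000, 5000, len(STARTS)).astype(float)
        prev = rng.random(len(STARTS)) * 5
        _, rate1 = total_prevalence(prev, PopulationPyramid(STARTS, counts))
        _, rate2 = total_prevalence(prev * 3, PopulationPyramid(STARTS, counts * 3))
        assert rate1 == pytest.approx(rate2)

    def test_empty_pyramid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            total_prevalence(np.array([0.0]), PopulationPyramid([0], [0]))

    def test_lifetime_conservation_under_full_penetrance(self):
        # uniform pyramid, lifelong survival: total new cases = f * N_bin
        pyramid = PopulationPyramid(STARTS, np.full(len(STARTS), 10_000.0))
        onset = OnsetDistribution(STARTS, np.ones(len(STARTS)))
        m = expected_new_cases(2e-3, pyramid, normalize_onset(onset))
        assert m.sum() == pytest.approx(2e-3 * 10_000.0)
        prev = apply_survival(m, None)
        assert prev[-1] == pytest.approx(m.sum())


class TestLiteratureDerivations:
    def test_c9ftd_published_inputs(self):
        out = reported_prevalence_c9ftd((0.04, 0.29), 83.5)
        assert out == {"low": 3.3, "high": 24.2, "mean": 13.78}

    def test_c9ftd_degenerate_ranges(self):
        assert reported_prevalence_c9ftd((0.0, 0.0), 50.0) == {
            "low": 0.0, "high": 0.0, "mean": 0.0}
        out = reported_prevalence_c9ftd((0.1, 0.1), 80.0)
        assert out["low"] == out["high"] == 8.0

    def test_c9als_published_inputs(self):
        out = reported_prevalence_c9als()
        assert out["weight"] == pytest.approx(0.103)
        assert out["low"] == 0.5
        assert out["high"] == 1.2

    def test_c9als_zero_mutation_fractions(self):
        out = reported_prevalence_c9als(familial_mut_fraction=0, sporadic_mut_fraction=0)
        assert (out["low"], out["high"]) == (0.0, 0.0)

    def test_hd40_published_inputs_and_identities(self):
        assert reported_prevalence_hd40(0.074, 9.7) == 0.72
        assert reported_prevalence_hd40(0.0, 9.7) == 0.0
        assert reported_prevalence_hd40(1.0, 9.7) == 9.7


class TestHelpers:
    def test_yearly_bins_aggregate_onto_model_grid(self):
        starts = np.arange(0, 10)
        values = np.ones(10)
        agg_starts, agg = aggregate_bins(starts, values)
        assert agg_starts.tolist() == [0, 5]
        assert agg.tolist() == [5.0, 5.0]

    def test_synthetic_epi_inputs_satisfy_contracts(self):
        pyramid, onset, penetrance = simulate_epi_inputs(seed=3)
        assert abs(normalize_onset(onset).counts.sum() - 1.0) < 1e-12
        assert np.all(np.diff(penetrance.fractions) >= 0)
        assert np.all(np.diff(pyramid.bin_starts) == BIN_WIDTH)
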