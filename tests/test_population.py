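"""Population error, power, and reliability attenuation formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepplan import (
    DegenerateDecompositionError,
    DomainError,
    PairedComparison,
    PowerSpec,
    SubjectPopulation,
    asymptotic_sigma_subjects,
    disattenuate,
    error_population,
    error_population_n,
    reliability_at_n,
    round_count,
    sample_size,
    sigma_subjects_at_n,
    t_statistic,
)

PRINTED_Z_SUM = 2.80  # two-decimal z_{0.975}+z_{0.8}, multiplier 15.68


def paper_power():
    return PowerSpec(alpha=0.05, beta=0.20, z_sum=PRINTED_Z_SUM)


class TestPopulationError:
    def test_published_value(self):
        # 20 subjects with between-subject CV 0.39 pin the population mean
        # to about +/-17.1%
        assert error_population(20, 0.39) == pytest.approx(0.171, abs=5e-4)

    def test_zero_cv(self):
        assert error_population(20, 0.0) == 0.0

    def test_sqrt_scaling(self):
        assert error_population(80, 0.39) == pytest.approx(error_population(20, 0.39) / 2, rel=1e-12)


class TestVarianceDecomposition:
    def test_forward(self):
        pop = SubjectPopulation(1.0, 0.5, 0.5)
        assert sigma_subjects_at_n(pop, 10) == pytest.approx(math.sqrt(0.275), rel=1e-12)
        assert sigma_subjects_at_n(pop, math.inf) == 0.5

    def test_no_trial_noise(self):
        pop = SubjectPopulation(1.0, 0.5, 0.0)
        for n in (1, 10, math.inf):
            assert sigma_subjects_at_n(pop, n) == 0.5

    def test_roundtrip(self):
        pop = SubjectPopulation(1.0, 0.5, 0.5)
        obs = sigma_subjects_at_n(pop, 10)
        assert asymptotic_sigma_subjects(obs, 0.5, 10) == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_guard(self):
        # observed spread smaller than the trial noise floor: 0.04 < 1/10
        with pytest.raises(DegenerateDecompositionError):
            asymptotic_sigma_subjects(0.2, 1.0, 10)

    def test_zero_noise_identity(self):
        assert asymptotic_sigma_subjects(0.4, 0.0, 10) == pytest.approx(0.4)


class TestErrorPopulationN:
    @pytest.mark.parametrize("sigma_t, n, expected", [
        (0.5, math.inf, 0.219),
        (0.5, 10, 0.230),
        (0.5, 5, 0.240),
        (1.0, 10, 0.259),
    ])
    def test_published_values(self, sigma_t, n, expected):
        pop = SubjectPopulation(mu_subjects=1.0, sigma_subjects=0.5, sigma_trials=sigma_t)
        assert error_population_n(pop, 20, n) == pytest.approx(expected, abs=5e-4)

    def test_infinite_trials_equals_subject_cv_formula(self):
        # at n = inf the two-level error collapses to the one-level formula
        # with CV_subjects = sigma_s / mu_s
        for mu, ss, st_ in [(1.0, 0.5, 0.5), (1.48, 0.57, 1.01), (2.0, 0.2, 1.0)]:
            pop = SubjectPopulation(mu, ss, st_)
            for N in (5, 20, 100):
                assert error_population_n(pop, N, math.inf) == pytest.approx(
                    error_population(N, ss / mu), rel=1e-12)


class TestTStatistic:
    def test_null_difference(self):
        cmp = PairedComparison(1.0, 1.0, 0.5, 0.5, 0.0)
        assert t_statistic(cmp, 20, 10) == 0.0

    def test_antisymmetric(self):
        a = PairedComparison(1.4, 1.0, 0.5, 0.5, 0.0)
        b = PairedComparison(1.0, 1.4, 0.5, 0.5, 0.0)
        assert t_statistic(a, 20, 10) == pytest.approx(-t_statistic(b, 20, 10), rel=1e-12)

    def test_unpaired_matches_textbook_formula(self):
        # with r = 0 the statistic must equal the equal-N unpaired t with
        # per-group variance sigma_s**2 + sigma_t**2/n (independent route)
        mu1, mu2, ss, st_, N, n = 1.4, 1.0, 0.5, 0.5, 20, 100
        per_group_var = ss**2 + st_**2 / n
        textbook = (mu1 - mu2) / math.sqrt(per_group_var * (1 / N + 1 / N))
        cmp = PairedComparison(mu1, mu2, ss, st_, 0.0)
        assert t_statistic(cmp, N, n) == pytest.approx(textbook, rel=1e-12)

    def test_increasing_in_n_and_N(self):
        cmp = PairedComparison(1.2, 1.0, 0.5, 0.5, 0.9)
        ts_n = [t_statistic(cmp, 20, n) for n in (1, 5, 20, 100, math.inf)]
        assert np.all(np.diff(ts_n) > 0)
        ts_N = [t_statistic(cmp, N, 10) for N in (2, 10, 40)]
        assert np.all(np.diff(ts_N) > 0)

    def test_degenerate(self):
        with pytest.raises(DegenerateDecompositionError):
            t_statistic(PairedComparison(1.2, 1.0, 0.0, 0.0, 0.0), 20, 10)
        with pytest.raises(DomainError):
            t_statistic(PairedComparison(1.2, 1.0, 0.5, 0.5, 0.0), 1, 10)


class TestSampleSize:
    def test_between_design_one_trial(self):
        cmp = PairedComparison(1.2, 1.0, 0.5, 0.5, 0.0)  # delta 0.2
        assert round_count(sample_size(cmp, paper_power(), 1), "ceil") == 196

    def test_within_design_ten_trials(self):
        cmp = PairedComparison(1.2, 1.0, 0.5, 0.5, 0.9)
        raw = sample_size(cmp, paper_power(), 10)
        assert raw == pytest.approx(19.6, abs=0.01)
        assert round_count(raw, "ceil") == 20

    @pytest.mark.parametrize("r, grid, expected", [
        # published unpaired and paired sample-size tables (ceil-rounded)
        (0.0, (1, 5, 10, 20, 40, math.inf), (196, 118, 108, 103, 101, 98)),
        (0.9, (1, 5, 10, 20, 30, 40, math.inf), (108, 30, 20, 15, 14, 13, 10)),
    ])
    def test_published_grids(self, r, grid, expected):
        cmp = PairedComparison(1.2, 1.0, 0.5, 0.5, r)
        got = tuple(int(round_count(sample_size(cmp, paper_power(), n), "ceil"))
                    for n in grid)
        assert got == expected

    def test_planning_example_six_subjects(self):
        cmp = PairedComparison(1.23, 0.62, 0.57, 1.01, 0.61)
        raw = sample_size(cmp, paper_power(), math.inf)
        assert raw == pytest.approx(5.34, abs=0.01)
        assert round_count(raw, "ceil") == 6

    def test_multiplier_emerges_from_alpha_beta(self):
        # 2 * (z_{0.975} + z_{0.8})**2 is approximately the printed 15.68,
        # computed, never hard-coded
        spec = PowerSpec(alpha=0.05, beta=0.20)
        assert 2 * spec.z_sum**2 == pytest.approx(15.698, abs=1e-3)

    def test_power_roundtrip(self):
        # the t statistic evaluated at the unrounded optimal N is exactly
        # the z-sum the power spec demanded
        spec = PowerSpec(alpha=0.05, beta=0.20)
        for r, n in [(0.0, 5), (0.61, math.inf), (0.9, 10)]:
            cmp = PairedComparison(1.23, 0.62, 0.57, 1.01, r)
            N = sample_size(cmp, spec, n)
            assert t_statistic(cmp, N, n) == pytest.approx(spec.z_sum, abs=1e-9)

    def test_monotone_in_n_and_r(self):
        spec = PowerSpec()
        sizes_n = [sample_size(PairedComparison(1.2, 1.0, 0.5, 0.5, 0.5), spec, n)
                   for n in (1, 5, 10, 100, math.inf)]
        assert np.all(np.diff(sizes_n) < 0)
        sizes_r = [sample_size(PairedComparison(1.2, 1.0, 0.5, 0.5, r), spec, 10)
                   for r in (-0.5, 0.0, 0.5, 0.9)]
        assert np.all(np.diff(sizes_r) < 0)

    def test_infinite_n_limit_drops_trial_noise(self):
        spec = PowerSpec()
        cmp = PairedComparison(1.2, 1.0, 0.5, 0.5, 0.5)
        no_noise = PairedComparison(1.2, 1.0, 0.5, 0.0, 0.5)
        assert sample_size(cmp, spec, math.inf) == pytest.approx(
            sample_size(no_noise, spec, 1), rel=1e-12)

    def test_equal_means_error(self):
        with pytest.raises(DomainError):
            sample_size(PairedComparison(1.0, 1.0, 0.5, 0.5, 0.0), PowerSpec(), 10)


class TestReliability:
    def test_attenuation_value(self):
        assert reliability_at_n(0.9, 0.5, 0.5, 10) == pytest.approx(0.9 * 0.25 / 0.275, rel=1e-12)

    def test_no_noise_identity(self):
        assert reliability_at_n(0.8, 0.5, 0.0, 10) == 0.8

    def test_zero_r_stays_zero(self):
        for n in (1, 10, math.inf):
            assert reliability_at_n(0.0, 0.5, 0.5, n) == 0.0

    def test_zero_subject_variance(self):
        assert reliability_at_n(0.9, 0.0, 0.5, 10) == 0.0

    def test_attenuation_bounded_by_asymptote(self):
        for n in (1, 5, 20, 100):
            assert abs(reliability_at_n(0.9, 0.5, 0.5, n)) <= 0.9
        assert reliability_at_n(0.9, 0.5, 0.5, math.inf) == pytest.approx(0.9)

    def test_disattenuation_value(self):
        got = disattenuate(0.8, math.sqrt(0.275), 0.5, 10)
        assert got.value == pytest.approx(0.8 * 0.275 / 0.25, rel=1e-10)
        assert got.in_bounds

    def test_out_of_bounds_flagged_not_clipped(self):
        got = disattenuate(0.95, math.sqrt(0.275), 0.5, 10)
        assert got.value > 1.0
        assert not got.in_bounds

    def test_degenerate_guard(self):
        with pytest.raises(DegenerateDecompositionError):
            disattenuate(0.5, 0.2, 1.0, 10)

    @given(r=st.floats(-1.0, 1.0), sigma_s=st.floats(0.1, 2.0),
           sigma_t=st.floats(0.0, 2.0), n=st.integers(1, 1000))
    @settings(derandomize=True, max_examples=80)
    def test_attenuate_disattenuate_inverse(self, r, sigma_s, sigma_t, n):
        r_n = reliability_at_n(r, sigma_s, sigma_t, n)
        obs = math.sqrt(sigma_s**2 + sigma_t**2 / n)
        assert disattenuate(r_n, obs, sigma_t, n).value == pytest.approx(r, abs=1e-12)
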