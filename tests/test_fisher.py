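"""Tests for the closed-form Fisher information and its special functions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from powerlaw_coding import (
    DegenerateModelError,
    NeuronSubset,
    UnsupportedDimensionError,
    broken_power_fisher,
    critical_exponent,
    energy_aware_performance,
    energy_curve,
    eigenvalue_lambda,
    fisher_curve,
    fisher_finite,
    fisher_limit,
    harmonic_number,
    locate_fisher_kink,
    mutual_information_from_fisher,
    riemann_zeta,
    subset_fisher,
    susceptibility,
)
from powerlaw_coding.code import CodeSpec


class TestSpecialFunctions:
    def test_harmonic_number_basic_values(self):
        assert harmonic_number(0.0, 5) == 5.0
        assert math.isclose(harmonic_number(1.0, 3), 11 / 6, rel_tol=1e-15)

    def test_harmonic_number_converges_to_zeta(self):
        assert abs(harmonic_number(2.0, 10**6) - math.pi**2 / 6) < 1e-5

    def test_zeta_at_two_is_pi_squared_over_six(self):
        assert math.isclose(riemann_zeta(2.0), math.pi**2 / 6, rel_tol=1e-12)

    def test_zeta_tends_to_one_for_large_argument(self):
        assert abs(riemann_zeta(50.0) - 1.0) < 1e-12

    @pytest.mark.parametrize("x", [1.0, 0.5, 0.0, -3.0])
    def test_zeta_divergence_marker_at_and_below_one(self, x):
        assert riemann_zeta(x) == math.inf


class TestCriticalExponent:
    @pytest.mark.parametrize("D,expected", [(1, 3.0), (2, 2.0), (4, 1.5), (math.inf, 1.0)])
    def test_formula(self, D, expected):
        assert critical_exponent(D) == expected

    def test_rejects_dimension_below_one(self):
        with pytest.raises(ValueError):
            critical_exponent(0)


class TestFisherFinite:
    def test_neural_noise_only(self):
        # sigma1 = 0: information is H_N(alpha-2)/sigma0^2
        H = harmonic_number(1.0, 20)
        assert math.isclose(fisher_finite(3.0, 20, 0.1, 0.0), H / 0.01, rel_tol=1e-12)

    def test_plateau_at_input_noise_bound(self):
        assert math.isclose(fisher_finite(2.0, 10**5, 0.01, 0.01), 1e4, rel_tol=1e-3)

    def test_against_direct_summation_oracle(self):
        H = sum(n ** (-2.0) for n in range(1, 101))
        expected = H / (1e-4 + 1e-4 * H)
        got = fisher_finite(4.0, 100, 0.01, 0.01)
        assert math.isclose(got, expected, rel_tol=1e-12)
        assert math.isclose(got, 6.205e3, rel_tol=1e-3)

    def test_noiseless_code_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            fisher_finite(3.0, 10, 0.0, 0.0)

    def test_monotone_nondecreasing_in_population_size(self):
        values = [fisher_finite(4.0, N, 0.01, 0.01) for N in (1, 5, 10, 50, 200, 1000)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_converges_to_large_population_limit(self):
        limit = fisher_limit(4.0, 1, 0.01, 0.01)
        assert abs(fisher_finite(4.0, 10**5, 0.01, 0.01) / limit - 1) < 1e-4

    @given(alpha=st.floats(1.0, 6.0), N=st.integers(1, 200))
    def test_never_exceeds_input_noise_bound(self, alpha, N):
        assert fisher_finite(alpha, N, 0.01, 0.01) < 1.0 / 0.01**2


class TestFisherLimit:
    def test_d1_ball_factor_reduces_to_one(self):
        # V_1 = 2, so the denominator factor is exactly 1 and the D=1 curve
        # is zeta(alpha-2)/(sigma0^2 + sigma1^2 zeta(alpha-2))
        z = riemann_zeta(2.0)
        expected = z / (1e-4 + 1e-4 * z)
        assert math.isclose(fisher_limit(4.0, 1, 0.01, 0.01), expected, rel_tol=1e-12)
        assert math.isclose(fisher_limit(4.0, 1, 0.01, 0.01), 6.219e3, rel_tol=1e-3)

    @pytest.mark.parametrize("alpha", [1.1, 2.0, 2.5, 3.0])
    @pytest.mark.parametrize("sigma0", [0.001, 0.01, 0.1])
    def test_plateau_exactly_at_input_noise_bound(self, alpha, sigma0):
        assert fisher_limit(alpha, 1, sigma0, 0.01) == 1e4

    def test_depends_on_neural_noise_above_critical(self):
        assert fisher_limit(4.0, 1, 0.001, 0.01) != fisher_limit(4.0, 1, 0.1, 0.01)

    def test_strictly_decreasing_above_critical(self):
        grid = np.arange(3.01, 6.0, 0.05)
        vals = [fisher_limit(a, 1, 0.01, 0.01) for a in grid]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_infinite_dimension_uses_stirling_denominator(self):
        z = riemann_zeta(2.0)
        expected = z / (math.e * math.pi * 1e-4 / 2 + 1e-4 * z)
        assert math.isclose(fisher_limit(2.0, math.inf, 0.01, 0.01), expected, rel_tol=1e-12)

    def test_degenerate_without_input_noise_below_critical(self):
        with pytest.raises(DegenerateModelError):
            fisher_limit(2.0, 1, 0.01, 0.0)

    def test_kink_detected_at_critical_exponent(self):
        assert abs(locate_fisher_kink(D=1, step=0.005) - 3.0) <= 0.005
        assert abs(locate_fisher_kink(D=2, alpha_min=1.2, alpha_max=3.0, step=0.005) - 2.0) <= 0.005


class TestEigenvalueLambda:
    def test_reduces_to_neural_noise_variance(self):
        assert eigenvalue_lambda(3.0, 50, 0.2, 0.0) == pytest.approx(0.04)

    def test_large_population_value(self):
        got = eigenvalue_lambda(4.0, 10**6, 0.01, 0.01)
        assert math.isclose(got, 1e-4 * (1 + math.pi**2 / 6), rel_tol=1e-5)
        assert math.isclose(got, 2.6449e-4, rel_tol=1e-4)

    def test_consistent_with_susceptibility_norm(self):
        spec = CodeSpec(N=40, alpha=3.5, sigma0=0.02, sigma1=0.03)
        mu = susceptibility(spec, 0.8)
        expected = 0.02**2 + 0.03**2 * float(mu @ mu)
        assert math.isclose(eigenvalue_lambda(3.5, 40, 0.02, 0.03), expected, rel_tol=1e-12)


class TestEnergyAwarePerformance:
    def test_large_alpha_limit(self):
        got = energy_aware_performance(50.0, 1, 0.01, 0.01, gamma=1e-3)
        assert abs(got - (1.0 / 2e-4 - 1e-3)) < 1e-6

    def test_grid_argmax_at_critical_exponent(self):
        curve = energy_curve(D=1, sigma0=0.01, sigma_i=0.01, gamma=1e-3)
        assert curve.argmax_alpha == pytest.approx(3.0, abs=0.01)

    def test_below_critical_pays_energy_for_no_information(self):
        j2 = energy_aware_performance(2.0, 1, 0.01, 0.01, gamma=1e-3)
        j3 = energy_aware_performance(3.0, 1, 0.01, 0.01, gamma=1e-3)
        assert j2 < j3

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            energy_aware_performance(3.0, 1, 0.01, 0.01, gamma=0.0)
        with pytest.raises(ValueError):
            energy_aware_performance(3.0, 1, 0.01, 0.01, gamma=-1.0)

    def test_finite_population_uses_harmonic_energy(self):
        got = energy_aware_performance(3.0, 1, 0.01, 0.01, gamma=1e-2, N=100)
        expected = fisher_finite(3.0, 100, 0.01, 0.01) - 1e-2 * harmonic_number(3.0, 100)
        assert math.isclose(got, expected, rel_tol=1e-12)
        with pytest.raises(UnsupportedDimensionError):
            energy_aware_performance(3.0, 2, 0.01, 0.01, gamma=1e-2, N=100)


class TestSubsetFisher:
    def test_full_set_matches_finite_formula(self):
        subset = NeuronSubset.full(30)
        assert math.isclose(
            subset_fisher(subset, 3.5, 0.01, 0.02),
            fisher_finite(3.5, 30, 0.01, 0.02),
            rel_tol=1e-12,
        )

    def test_single_lowest_mode(self):
        assert math.isclose(
            subset_fisher(NeuronSubset((1,)), 2.0, 0.1, 0.2), 1.0 / (0.01 + 0.04), rel_tol=1e-12
        )

    def test_low_modes_carry_more_information(self):
        low = NeuronSubset(tuple(range(1, 11)))
        high = NeuronSubset(tuple(range(11, 21)))
        assert subset_fisher(low, 3.0, 0.01, 0.01) > subset_fisher(high, 3.0, 0.01, 0.01)


class TestBrokenPowerLaw:
    def test_equal_exponents_reduce_to_single_power_law(self):
        got = broken_power_fisher(2.5, 2.5, 7, 50, 0.01, 0.01)
        assert math.isclose(got, fisher_finite(2.5, 50, 0.01, 0.01), rel_tol=1e-12)

    def test_break_at_end_ignores_second_exponent(self):
        got = broken_power_fisher(1.8, 5.0, 50, 50, 0.01, 0.01)
        assert math.isclose(got, fisher_finite(1.8, 50, 0.01, 0.01), rel_tol=1e-12)

    def test_against_explicit_spectrum_oracle(self):
        a1, a2, nb, N, s0, s1 = 0.5, 1.2, 10, 1000, 0.01, 0.01
        # oracle: build the continuous broken amplitude spectrum explicitly
        amps = []
        cb = nb ** ((a2 - a1) / 2.0)
        for n in range(1, N + 1):
            amps.append(n ** (-a1 / 2.0) if n <= nb else cb * n ** (-a2 / 2.0))
        H = sum((n * a) ** 2 for n, a in zip(range(1, N + 1), amps))
        expected = H / (s0**2 + s1**2 * H)
        assert math.isclose(broken_power_fisher(a1, a2, nb, N, s0, s1), expected, rel_tol=1e-12)

    def test_information_increases_as_exponents_decrease(self):
        base = broken_power_fisher(0.5, 1.2, 10, 1000, 0.01, 0.01)
        assert broken_power_fisher(0.4, 1.2, 10, 1000, 0.01, 0.01) > base
        assert broken_power_fisher(0.5, 1.1, 10, 1000, 0.01, 0.01) > base

    def test_break_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            broken_power_fisher(0.5, 1.2, 0, 10, 0.01, 0.01)
        with pytest.raises(ValueError):
            broken_power_fisher(0.5, 1.2, 11, 10, 0.01, 0.01)


class TestMutualInformation:
    def test_monotone_in_fisher_information(self):
        assert mutual_information_from_fisher(1e4) > mutual_information_from_fisher(1e3)

    def test_zero_crossing(self):
        # 2*pi*e / I = (2*pi)^2  <=>  I = e/(2*pi), where the two terms cancel
        assert abs(mutual_information_from_fisher(math.e / (2 * math.pi))) < 1e-12

    def test_uniform_prior_value(self):
        # log(2 pi) - 0.5 log(2 pi e / 1e4), evaluated independently
        assert math.isclose(
            mutual_information_from_fisher(1e4), 5.024108719192764, rel_tol=1e-12
        )

    def test_explicit_uniform_prior_matches_default(self):
        uniform = lambda t: np.full_like(t, 1.0 / (2 * math.pi))
        assert math.isclose(
            mutual_information_from_fisher(123.0, prior=uniform),
            mutual_information_from_fisher(123.0),
            rel_tol=1e-9,
        )

    def test_rejects_nonpositive_information(self):
        with pytest.raises(ValueError):
            mutual_information_from_fisher(0.0)


class TestCurveContainers:
    def test_fisher_curve_matches_pointwise_calls(self):
        grid = np.arange(3.1, 4.0, 0.1)
        curve = fisher_curve(grid, D=2, sigma0=0.01, sigma_i=0.01)
        expected = [fisher_limit(a, 2, 0.01, 0.01) for a in grid]
        np.testing.assert_allclose(curve.values, expected, rtol=1e-12)

    def test_energy_curve_serialization(self, tmp_path):
        curve = energy_curve(np.arange(2.0, 4.0, 0.5), D=1, gamma=1e-3)
        csv_path, json_path = curve.save(tmp_path / "energy")
        assert csv_path.exists() and json_path.exists()
        import pandas as pd

        df = pd.read_csv(csv_path)
        assert list(df.columns) == ["alpha", "value"]
        assert len(df) == 4
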