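"""Kinetic rate laws and their one-parameter constrained fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biosorb.errors import DegenerateInputError, InvalidInputError
from biosorb.kinetics import (
    TimeCourse,
    first_order_adsorbed,
    first_order_remaining,
    fit_first_order,
    fit_second_order,
    second_order_adsorbed,
    second_order_remaining,
)

from conftest import grid_search_rate

TIMES = np.array([0.0, 24.0, 48.0, 72.0, 96.0])


class TestModelCurves:
    def test_first_order_remaining_values(self):
        assert first_order_remaining(50.0, 0.052, 0.0) == pytest.approx(50.0)
        assert first_order_remaining(50.0, 0.052, 24.0) == pytest.approx(14.3539, abs=5e-4)
        assert first_order_remaining(50.0, 0.0, 1000.0) == pytest.approx(50.0)

    def test_first_order_adsorbed_values(self):
        assert first_order_adsorbed(50.0, 0.052, 0.0) == 0.0
        # asymptote: the fixed equilibrium capacity 0.91 * Ci
        assert first_order_adsorbed(50.0, 0.052, 1e6) == pytest.approx(45.5)
        # 22.75 * (1 - exp(-0.046 * 48)), recomputed by hand
        assert first_order_adsorbed(25.0, 0.046, 48.0) == pytest.approx(20.2489, abs=5e-4)

    def test_second_order_remaining_values(self):
        assert second_order_remaining(50.0, 0.0018, 0.0) == pytest.approx(50.0)
        # 1 / (0.0432 + 0.02)
        assert second_order_remaining(50.0, 0.0018, 24.0) == pytest.approx(15.823, abs=1e-3)
        assert second_order_remaining(50.0, 0.0, 1000.0) == pytest.approx(50.0)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InvalidInputError):
            first_order_remaining(50.0, 0.05, -1.0)
        with pytest.raises(InvalidInputError):
            first_order_adsorbed(50.0, 0.05, 1.0, equilibrium_fraction=1.5)
        with pytest.raises(InvalidInputError):
            second_order_remaining(-1.0, 0.001, 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        ci=st.floats(min_value=1.0, max_value=200.0),
        k1=st.floats(min_value=1e-4, max_value=0.5),
        t=st.floats(min_value=0.0, max_value=200.0),
    )
    def test_mass_balance_between_remaining_and_adsorbed_forms(self, ci, k1, t):
        """Ci*e^{-Kt} plus the adsorbed amount implied by the same K under
        the pure-exponential form sums to Ci at every t."""
        remaining = first_order_remaining(ci, k1, t)
        adsorbed_full = first_order_adsorbed(ci, k1, t, equilibrium_fraction=1.0)
        assert remaining + adsorbed_full == pytest.approx(ci, rel=1e-12)

    def test_monotonicity_and_convexity(self):
        t = np.linspace(0.0, 96.0, 200)
        ct1 = first_order_remaining(50.0, 0.052, t)
        ct2 = second_order_remaining(50.0, 0.0018, t)
        q1 = first_order_adsorbed(50.0, 0.052, t)
        assert np.all(np.diff(ct1) < 0)
        assert np.all(np.diff(ct2) < 0)
        assert np.all(np.diff(q1) > 0)
        assert np.all(np.diff(ct2, 2) > 0)  # second-order decay is convex


class TestTimeCourse:
    def test_validation(self):
        with pytest.raises(InvalidInputError):
            TimeCourse(50.0, np.array([1.0, 2.0]), np.zeros((1, 2)))  # no t=0
        with pytest.raises(InvalidInputError):
            TimeCourse(50.0, np.array([0.0, 2.0, 2.0]), np.zeros((1, 3)))
        with pytest.raises(InvalidInputError):
            TimeCourse(50.0, TIMES, np.zeros((1, 3)))  # shape mismatch

    def test_scale_conversion_round_trip(self):
        ct = second_order_remaining(50.0, 0.0018, TIMES)
        tc = TimeCourse(50.0, TIMES, ct[None, :], value_kind="remaining")
        np.testing.assert_allclose(tc.adsorbed(), 50.0 - ct[None, :])
        np.testing.assert_allclose(tc.remaining(), ct[None, :])


class TestFirstOrderFit:
    def test_noiseless_self_consistency(self):
        q = first_order_adsorbed(50.0, 0.05, TIMES)
        tc = TimeCourse(50.0, TIMES, q[None, :], value_kind="adsorbed")
        fit = fit_first_order(tc)
        assert fit.rate_constant == pytest.approx(0.05, abs=1e-8)
        assert fit.residual_rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.fixed_qe == pytest.approx(45.5)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        rng = np.random.default_rng(7)
        q = first_order_adsorbed(50.0, 0.052, TIMES) + rng.normal(0, 1.0, TIMES.size)
        q = np.clip(q, 0, None)
        tc = TimeCourse(50.0, TIMES, q[None, :], value_kind="adsorbed")
        fit = fit_first_order(tc)

        def ssr(k):
            return np.sum((q - first_order_adsorbed(50.0, k, TIMES)) ** 2)

        assert fit.rate_constant == pytest.approx(grid_search_rate(ssr), abs=1e-5)

    def test_misspecified_data_still_converges(self, second_order_tc):
        fit = fit_first_order(second_order_tc)
        assert fit.rate_constant > 0
        assert fit.residual_rmse > 0

    def test_degenerate_inputs_rejected(self):
        t2 = np.array([0.0, 24.0])
        with pytest.raises(DegenerateInputError):
            fit_first_order(TimeCourse(50.0, t2, np.zeros((1, 2)), value_kind="adsorbed"))
        with pytest.raises(DegenerateInputError):
            fit_first_order(TimeCourse(50.0, TIMES, np.zeros((1, 5)), value_kind="adsorbed"))

    def test_pooled_replicates_enter_individually(self):
        """Fitting two replicates with symmetric offsets reproduces the
        noiseless single-curve estimate (pooled residuals cancel)."""
        q = first_order_adsorbed(50.0, 0.05, TIMES)
        offset = np.array([0.0, 0.5, -0.3, 0.2, -0.4])
        values = np.vstack([q + offset, q - offset])
        tc = TimeCourse(50.0, TIMES, values, value_kind="adsorbed")
        fit = fit_first_order(tc)
        assert fit.n_obs == 10
        assert fit.rate_constant == pytest.approx(0.05, abs=1e-6)


class TestSecondOrderFit:
    def test_noiseless_self_consistency(self):
        ct = second_order_remaining(50.0, 0.002, TIMES)
        tc = TimeCourse(50.0, TIMES, ct[None, :], value_kind="remaining")
        for method in ("nls", "linearized"):
            fit = fit_second_order(tc, method=method)
            assert fit.rate_constant == pytest.approx(0.002, abs=1e-8), method

    def test_matches_grid_search_oracle_on_noisy_data(self):
        rng = np.random.default_rng(11)
        ct = second_order_remaining(50.0, 0.0018, TIMES) + rng.normal(0, 1.1, TIMES.size)
        tc = TimeCourse(50.0, TIMES, ct[None, :], value_kind="remaining")
        fit = fit_second_order(tc)

        def ssr(k):
            return np.sum((ct - second_order_remaining(50.0, k, TIMES)) ** 2)

        oracle = grid_search_rate(ssr, lo=1e-6, hi=0.05)
        assert fit.rate_constant == pytest.approx(oracle, abs=1e-6)

    def test_nonpositive_concentrations_rejected(self):
        ct = second_order_remaining(50.0, 0.002, TIMES).copy()
        ct[-1] = 0.0
        tc = TimeCourse(50.0, TIMES, ct[None, :], value_kind="remaining")
        with pytest.raises(InvalidInputError):
            fit_second_order(tc)

    def test_two_time_points_rejected(self):
        t2 = np.array([0.0, 24.0])
        tc = TimeCourse(50.0, t2, np.array([[50.0, 30.0]]), value_kind="remaining")
        with pytest.raises(DegenerateInputError):
            fit_second_order(tc)

    def test_adsorbed_form_respects_mass_balance(self):
        q = second_order_adsorbed(50.0, 0.0018, TIMES)
        ct = second_order_remaining(50.0, 0.0018, TIMES)
        np.testing.assert_allclose(q + ct, 50.0, rtol=1e-12)
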