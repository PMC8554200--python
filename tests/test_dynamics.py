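"""Holling-LV dynamics: right-hand side, RK4 solver, decomposition,
classical growth curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hollimap.dynamics import (
    ClassicalGrowthParams,
    HollingLVParams,
    StatePair,
    TrajectoryDivergenceError,
    classical_growth_curve,
    decompose_trajectory,
    holling_lv_rhs,
    logistic_closed_form,
    solve_holling_lv,
)


class TestRHS:
    def test_zero_state_is_fixed_point(self, theta):
        assert holling_lv_rhs(StatePair(0.0, 0.0), theta) == (0.0, 0.0)

    def test_logistic_equilibrium_without_interaction(self):
        p = HollingLVParams(0.5, 24.0, 0.0, 0.4, 21.0, 0.0)
        dE, dS = holling_lv_rhs((24.0, 21.0), p)
        assert dE == pytest.approx(0.0, abs=1e-12)
        assert dS == pytest.approx(0.0, abs=1e-12)

    def test_hand_derived_value(self, theta):
        # term-by-term: 0.5*5*(19/24) + 0.5*5*(-0.01/6)*5 and the S analogue
        dE, dS = holling_lv_rhs((5.0, 5.0), theta)
        assert dE == pytest.approx(47.0 / 24.0, rel=1e-12)
        assert dS == pytest.approx(1.4904761904761905, rel=1e-12)

    def test_interaction_term_sign_follows_alpha(self):
        pos = HollingLVParams(0.5, 24.0, 0.3, 0.4, 21.0, -0.3)
        base = HollingLVParams(0.5, 24.0, 0.0, 0.4, 21.0, 0.0)
        dE_pos, dS_pos = holling_lv_rhs((5.0, 5.0), pos)
        dE_0, dS_0 = holling_lv_rhs((5.0, 5.0), base)
        assert dE_pos > dE_0
        assert dS_pos < dS_0

    def test_nonfinite_state_rejected(self, theta):
        with pytest.raises(ValueError):
            holling_lv_rhs((np.nan, 1.0), theta)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HollingLVParams(-0.1, 24.0, 0.0, 0.4, 21.0, 0.0)
        with pytest.raises(ValueError):
            HollingLVParams(0.5, 0.0, 0.0, 0.4, 21.0, 0.0)
        with pytest.raises(ValueError):
            HollingLVParams(0.5, 24.0, np.inf, 0.4, 21.0, 0.0)


class TestSolver:
    @pytest.mark.parametrize("r,K,x0", [(0.5, 24.0, 0.8), (0.2, 10.0, 2.0), (0.9, 50.0, 0.1)])
    def test_matches_logistic_closed_form_without_interaction(self, r, K, x0, times16):
        p = HollingLVParams(r, K, 0.0, r, K, 0.0)
        tr = solve_holling_lv(p, (x0, x0), times16, step=0.01)
        expected = logistic_closed_form(r, K, x0, times16 - times16[0])
        assert np.max(np.abs(tr.E_values - expected)) < 1e-6
        assert np.max(np.abs(tr.S_values - expected)) < 1e-6

    def test_zero_rates_give_constant_trajectory(self, times16):
        p = HollingLVParams(0.0, 24.0, -0.1, 0.0, 21.0, -0.1)
        tr = solve_holling_lv(p, (3.0, 4.0), times16)
        assert np.allclose(tr.E_values, 3.0)
        assert np.allclose(tr.S_values, 4.0)

    def test_fourth_order_convergence(self, theta):
        # halving the step should cut the error against a fine reference ~16x
        times = np.array([0.0, 8.0])
        ref = solve_holling_lv(theta, (0.8, 0.8), times, step=0.001).E_values[-1]
        errs = []
        for h in (0.4, 0.2):
            v = solve_holling_lv(theta, (0.8, 0.8), times, step=h).E_values[-1]
            errs.append(abs(v - ref))
        ratio = errs[0] / errs[1]
        assert 8.0 < ratio < 32.0

    def test_non_integer_observation_times(self, theta):
        times = np.array([1.37, 2.9113, 7.25, 19.000001])
        tr = solve_holling_lv(theta, (0.8, 0.8), times, step=0.01)
        assert np.all(np.isfinite(tr.E_values))
        assert np.all(np.diff(tr.E_values) > 0)

    def test_divergence_raises_with_time(self):
        p = HollingLVParams(1.0, 1.0, 6.0, 1.0, 1.0, 6.0)
        with pytest.raises(TrajectoryDivergenceError) as err:
            solve_holling_lv(p, (100.0, 100.0), np.array([0.0, 100.0]), step=0.5)
        assert np.isfinite(err.value.time)

    def test_rejects_bad_grids(self, theta):
        with pytest.raises(ValueError):
            solve_holling_lv(theta, (1.0, 1.0), np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            solve_holling_lv(theta, (1.0, 1.0), np.array([1.0, 2.0]), step=-0.1)


class TestDecomposition:
    def test_zero_interaction_gives_zero_dependent(self, times16):
        p = HollingLVParams(0.5, 24.0, 0.0, 0.4, 21.0, 0.0)
        dec = decompose_trajectory(p, (0.8, 0.8), times16, step=0.01)
        assert np.max(np.abs(dec.dependent_E)) < 1e-6
        assert np.max(np.abs(dec.dependent_S)) < 1e-6

    @given(
        a_es=st.floats(-0.3, 0.3),
        a_se=st.floats(-0.3, 0.3),
    )
    @settings(max_examples=20, deadline=None)
    def test_conservation_exact(self, a_es, a_se):
        p = HollingLVParams(0.5, 24.0, a_es, 0.4, 21.0, a_se)
        t = np.linspace(0.0, 30.0, 8)
        dec = decompose_trajectory(p, (0.8, 0.8), t, step=0.05)
        # dependent is defined as net - independent: the identity holds to
        # machine precision (one rounding in the subtraction, one in the sum)
        np.testing.assert_allclose(
            dec.net_E, dec.independent_E + dec.dependent_E, rtol=1e-12, atol=1e-12
        )
        np.testing.assert_allclose(
            dec.net_S, dec.independent_S + dec.dependent_S, rtol=1e-12, atol=1e-12
        )

    def test_mutual_antagonism_gives_nonpositive_dependent(self, theta, times16):
        dec = decompose_trajectory(theta, (0.8, 0.8), times16, step=0.01)
        assert np.all(dec.dependent_E <= 1e-12)
        assert np.all(dec.dependent_S <= 1e-12)


class TestClassicalCurves:
    def test_logistic_asymptote_is_K(self):
        p = ClassicalGrowthParams("logistic", K=23.94, a=0.29, b=0.22)
        assert classical_growth_curve(p, [1000.0])[0] == pytest.approx(23.94, rel=1e-6)

    def test_gompertz_at_zero(self):
        p = ClassicalGrowthParams("gompertz", K=20.0, a=1.5, b=0.2)
        assert classical_growth_curve(p, [0.0])[0] == pytest.approx(20.0 * np.exp(-1.5))

    def test_richards_reduces_to_logistic_at_m_one(self):
        t = np.linspace(0.0, 40.0, 30)
        rich = classical_growth_curve(
            ClassicalGrowthParams("richards", K=24.0, a=0.9, b=0.15, m=1.0), t
        )
        logi = classical_growth_curve(
            ClassicalGrowthParams("logistic", K=24.0, a=0.9, b=0.15), t
        )
        np.testing.assert_allclose(rich, logi, rtol=1e-12)

    def test_negative_shape_parameters_representable(self):
        # fitted shape values below zero occur in practice and must evaluate
        p = ClassicalGrowthParams("richards", K=24.74, a=0.90, b=0.10, m=-1.25)
        vals = classical_growth_curve(p, np.linspace(0, 36, 16))
        assert np.all(np.isfinite(vals))

    def test_richards_zero_m_rejected(self):
        with pytest.raises(ValueError):
            ClassicalGrowthParams("richards", K=24.0, a=0.9, b=0.15, m=0.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ClassicalGrowthParams("weibull", K=24.0, a=0.9, b=0.15)
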