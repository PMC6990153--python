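import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from ikrfit.model import (
    FARADAY_CONSTANT,
    GAS_CONSTANT,
    GateState,
    IonicConditions,
    ModelEvaluationError,
    ModelParameters,
    analytic_step_solution,
    current,
    gate_summary,
    nernst,
    ode_rhs,
    steady_state,
    summary_curves,
    transition_rates,
)
from ikrfit.synthetic import sample_plausible_params

# strategy: log-uniform pre-factors and moderate sensitivities, the regime
# the protocols can actually probe
pre = st.floats(1e-6, 1.0)
sens = st.floats(1e-3, 0.2)
param_sets = st.builds(
    ModelParameters,
    p1=pre, p2=sens, p3=pre, p4=sens, p5=pre, p6=sens, p7=pre, p8=sens,
    p9=st.floats(1e-3, 10.0),
)


class TestModelParameters:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(0.0, 1, 1, 1, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            ModelParameters(1, 1, 1, 1, 1, 1, 1, -2, 1)
        with pytest.raises(ValueError):
            ModelParameters(1, 1, 1, 1, np.nan, 1, 1, 1, 1)

    def test_array_round_trip(self, params):
        assert ModelParameters.from_array(params.as_array()) == params

    def test_json_round_trip(self, tmp_path, params):
        path = tmp_path / "p.json"
        params.save(path)
        assert ModelParameters.load(path) == params

    def test_key_value_format(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text(
            "\n".join(f"p{i}={v}" for i, v in enumerate(range(1, 10), start=1))
        )
        loaded = ModelParameters.load(path)
        assert loaded.p1 == 1.0 and loaded.p9 == 9.0


class TestTransitionRates:
    def test_rates_at_zero_voltage_equal_prefactors(self, params):
        k = transition_rates(params, 0.0)
        assert (k.k1, k.k2, k.k3, k.k4) == (
            params.p1, params.p3, params.p5, params.p7,
        )

    def test_exponent_exactly_one(self):
        p = ModelParameters(1.0, 0.01, 1, 1e-7, 1, 1e-7, 1, 1e-7, 1)
        assert transition_rates(p, 100.0).k1 == pytest.approx(math.e, rel=1e-12)

    def test_matches_scalar_formula_oracle(self, rng):
        for _ in range(10):
            p = sample_plausible_params(rng)
            for v in np.linspace(-120, 60, 19):
                k = transition_rates(p, float(v))
                assert k.k1 == pytest.approx(p.p1 * math.exp(p.p2 * v), rel=1e-12)
                assert k.k2 == pytest.approx(p.p3 * math.exp(-p.p4 * v), rel=1e-12)
                assert k.k3 == pytest.approx(p.p5 * math.exp(p.p6 * v), rel=1e-12)
                assert k.k4 == pytest.approx(p.p7 * math.exp(-p.p8 * v), rel=1e-12)

    def test_overflow_is_an_invalid_evaluation(self):
        p = ModelParameters(1, 0.4, 1, 0.4, 1, 0.4, 1, 0.4, 1)
        with pytest.raises(ModelEvaluationError):
            transition_rates(p, 1e5)

    def test_nonfinite_voltage_rejected(self, params):
        with pytest.raises(ValueError):
            transition_rates(params, float("nan"))


class TestGateSummary:
    def test_symmetric_rates_give_half_activation(self):
        p = ModelParameters(0.02, 0.05, 0.02, 0.05, 1, 0.01, 1, 0.01, 1)
        assert gate_summary(p, 0.0).a_inf == pytest.approx(0.5, abs=1e-15)

    def test_unit_rates_give_half_millisecond(self):
        p = ModelParameters(1.0, 1e-7, 1.0, 1e-7, 1, 0.01, 1, 0.01, 1)
        assert gate_summary(p, 0.0).tau_a == pytest.approx(0.5, rel=1e-9)

    def test_steady_state_monotonicity_on_dense_grid(self, rng):
        for _ in range(5):
            p = sample_plausible_params(rng)
            curves = summary_curves(p, np.linspace(-120, 60, 361))
            assert np.all(np.diff(curves["a_inf"]) > 0)
            assert np.all(np.diff(curves["r_inf"]) < 0)

    @given(param_sets, st.floats(-120, 60))
    @settings(max_examples=30, deadline=None)
    def test_algebraic_identities(self, p, v):
        s = gate_summary(p, v)
        k = transition_rates(p, v)
        assert s.a_inf / s.tau_a == pytest.approx(k.k1, rel=1e-12)
        assert s.r_inf / s.tau_r == pytest.approx(k.k4, rel=1e-12)
        assert 0 < s.a_inf < 1 and 0 < s.r_inf < 1
        assert s.tau_a > 0 and s.tau_r > 0


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst(5.4, 5.4, 300.0) == 0.0

    def test_log_e_gives_rt_over_f(self):
        k_in = 100.0
        expected = 1e3 * GAS_CONSTANT * 295.0 / FARADAY_CONSTANT
        assert nernst(k_in * math.e, k_in, 295.0) == pytest.approx(expected, rel=1e-12)

    def test_physiological_value(self):
        # independent constant-folding: (1e3 R T / F) ln(4/130)
        assert nernst(4.0, 130.0, 294.65) == pytest.approx(-88.39207122561936,
                                                           rel=1e-12)
        assert -89.0 < nernst(4.0, 130.0, 294.65) < -88.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nernst(-1.0, 130.0, 295.0)
        with pytest.raises(ValueError):
            nernst(4.0, 130.0, 0.0)

    def test_conditions_compute_reversal(self):
        cond = IonicConditions(4.0, 130.0, 294.65)
        assert cond.E_K == pytest.approx(nernst(4.0, 130.0, 294.65))


class TestCurrent:
    def test_zero_at_reversal(self, params):
        state = GateState(a=0.7, r=0.3)
        assert current(params, state, -85.0, -85.0) == 0.0

    def test_zero_when_gate_closed(self, params):
        assert current(params, GateState(a=0.0, r=0.9), 0.0, -88.0) == 0.0
        assert current(params, GateState(a=0.9, r=0.0), 0.0, -88.0) == 0.0

    def test_identity_scaling(self):
        p = ModelParameters(1, 1, 1, 1, 1, 1, 1, 1, 1.0)
        assert current(p, GateState(a=1.0, r=1.0), -78.0, -88.0) == pytest.approx(10.0)


class TestOdeRhs:
    def test_fixed_point(self, params):
        state = steady_state(params, -20.0)
        da, dr = ode_rhs(params, -20.0, state)
        assert abs(da) < 1e-15 and abs(dr) < 1e-15

    def test_direct_substitution(self):
        # choose rates so a_inf = 1 (k2 ~ 0) and tau_a = 2
        p = ModelParameters(0.5, 1e-7, 1e-12, 1e-7, 1, 0.01, 1, 0.01, 1)
        da, _ = ode_rhs(p, 0.0, GateState(a=0.0, r=0.5))
        assert da == pytest.approx(0.5, rel=1e-6)

    def test_matches_finite_difference_of_analytic_solution(self, rng):
        h = 1e-6
        for _ in range(5):
            p = sample_plausible_params(rng)
            state = GateState(a=float(rng.uniform(0, 1)), r=float(rng.uniform(0, 1)))
            v = float(rng.uniform(-100, 40))
            mid = analytic_step_solution(p, v, state, h)
            upper = analytic_step_solution(p, v, state, 2 * h)
            fd_a = (upper.a - state.a) / (2 * h)
            fd_r = (upper.r - state.r) / (2 * h)
            da, dr = ode_rhs(p, v, mid)
            assert fd_a == pytest.approx(da, rel=1e-5, abs=1e-12)
            assert fd_r == pytest.approx(dr, rel=1e-5, abs=1e-12)


class TestAnalyticStepSolution:
    def test_zero_time_is_identity(self, params):
        s0 = GateState(a=0.3, r=0.6, t=5.0)
        s1 = analytic_step_solution(params, 0.0, s0, 0.0)
        assert (s1.a, s1.r, s1.t) == (0.3, 0.6, 5.0)

    def test_long_time_reaches_steady_state(self, params):
        s = gate_summary(params, 10.0)
        horizon = 60.0 * max(s.tau_a, s.tau_r)
        out = analytic_step_solution(params, 10.0, GateState(a=0.0, r=1.0), horizon)
        assert out.a == pytest.approx(s.a_inf, abs=1e-15)
        assert out.r == pytest.approx(s.r_inf, abs=1e-15)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            analytic_step_solution(params, 0.0, GateState(a=0.5, r=0.5), -1.0)

    def test_matches_scipy_ode_oracle(self, rng):
        for _ in range(3):
            p = sample_plausible_params(rng)
            v = float(rng.uniform(-100, 40))
            s = gate_summary(p, v)
            a0, r0 = float(rng.uniform(0, 1)), float(rng.uniform(0, 1))
            horizon = 10.0 * max(s.tau_a, s.tau_r)
            t_eval = np.linspace(0, horizon, 50)
            sol = solve_ivp(
                lambda t, y: ode_rhs(p, v, GateState(a=y[0], r=y[1])),
                (0, horizon), [a0, r0], rtol=1e-8, atol=1e-8, t_eval=t_eval,
                method="LSODA",
            )
            for k, t in enumerate(t_eval):
                exact = analytic_step_solution(p, v, GateState(a=a0, r=r0), float(t))
                assert sol.y[0, k] == pytest.approx(exact.a, abs=1e-6)
                assert sol.y[1, k] == pytest.approx(exact.r, abs=1e-6)

    @given(param_sets, st.floats(-100, 40), st.floats(0, 1), st.floats(0, 1),
           st.floats(0.01, 500.0), st.floats(0.01, 500.0))
    @settings(max_examples=30, deadline=None)
    def test_semigroup_property(self, p, v, a0, r0, t1, t2):
        s0 = GateState(a=a0, r=r0)
        direct = analytic_step_solution(p, v, s0, t1 + t2)
        stepped = analytic_step_solution(p, v, analytic_step_solution(p, v, s0, t1), t2)
        assert stepped.a == pytest.approx(direct.a, rel=1e-12, abs=1e-12)
        assert stepped.r == pytest.approx(direct.r, rel=1e-12, abs=1e-12)

    @given(param_sets, st.floats(-120, 60), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_gates_stay_in_unit_square(self, p, v, a0, r0, t):
        out = analytic_step_solution(p, v, GateState(a=a0, r=r0), t)
        assert 0.0 <= out.a <= 1.0
        assert 0.0 <= out.r <= 1.0
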