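import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from ikrfit.model import ModelParameters
from ikrfit.optimize import (
    FitResult,
    OptimizerConfig,
    ParameterBounds,
    SearchTransform,
    default_bounds,
    in_bounds,
    multi_start,
    reliability,
    run_fit,
    sample_start_points,
    seeded_start_from_method1,
)


@pytest.fixture(scope="module")
def bounds():
    return default_bounds()


@pytest.fixture(scope="module")
def transform():
    return SearchTransform.default()


class TestInBounds:
    def test_default_fixture_is_feasible(self, params, bounds):
        assert in_bounds(params, bounds)

    def test_box_violation(self, params, bounds):
        theta = params.as_array()
        theta[0] = bounds.upper[0] * 2.0
        assert not in_bounds(theta, bounds)

    def test_rate_violation_matches_dense_grid_oracle(self, bounds):
        # inside every box but k1 exceeds k_max at the top of the voltage range
        theta = np.array([500.0, 0.2, 3.45e-5, 0.05, 0.0873, 0.0089,
                          5.15e-3, 0.0316, 0.1524])
        v_grid = np.linspace(bounds.v_lo, bounds.v_hi, 1000)
        k1 = theta[0] * np.exp(theta[1] * v_grid)
        assert np.max(k1) > bounds.k_max  # oracle
        assert np.all(theta >= bounds.lower) and np.all(theta <= bounds.upper)
        assert not in_bounds(theta, bounds)

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            ParameterBounds(np.ones(9), np.ones(9), 1e-5, 1e3, -120, 60)
        with pytest.raises(ValueError):
            ParameterBounds(np.ones(9), np.full(9, 2.0), 1.0, 0.5, -120, 60)


class TestSearchTransform:
    def test_round_trip(self, params, transform):
        x = transform.to_search(params)
        assert np.allclose(transform.from_search(x), params.as_array(), rtol=1e-14)

    def test_identity_is_noop(self, params):
        t = SearchTransform.identity()
        assert np.array_equal(t.to_search(params), params.as_array())

    def test_log_midpoint_is_geometric_mean(self, bounds, transform):
        lo_t, hi_t = transform.bounds_in_search_space(bounds)
        mid = transform.from_search((lo_t + hi_t) / 2.0)
        for i, is_log in enumerate(transform.log_mask):
            if is_log:
                geo = math.sqrt(bounds.lower[i] * bounds.upper[i])
                assert mid[i] == pytest.approx(geo, rel=1e-12)

    @given(st.lists(st.floats(1e-6, 1e3), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, values):
        t = SearchTransform.default()
        theta = np.asarray(values)
        assert np.allclose(t.from_search(t.to_search(theta)), theta, rtol=1e-12)


class TestStartPoints:
    def test_all_feasible(self, bounds, transform, rng):
        for x in sample_start_points(25, bounds, transform, rng):
            assert in_bounds(transform.from_search(x), bounds)

    def test_seeded_reproducibility(self, bounds, transform):
        a = sample_start_points(10, bounds, transform, np.random.default_rng(5))
        b = sample_start_points(10, bounds, transform, np.random.default_rng(5))
        assert np.array_equal(np.asarray(a), np.asarray(b))

    def test_marginal_matches_independent_rejection_sampler(self, bounds,
                                                            transform):
        """The marginal of log p1 is uniform-within-the-band: compare the
        sampler against an independently coded rejection sampler."""
        points = sample_start_points(
            1500, bounds, transform, np.random.default_rng(0)
        )
        log_p1 = np.array([x[0] for x in points])

        rng = np.random.default_rng(99)
        ref = []
        log_lo, log_hi = np.log(bounds.lower[0]), np.log(bounds.upper[0])
        while len(ref) < 1500:
            lp = rng.uniform(log_lo, log_hi)
            p2 = rng.uniform(bounds.lower[1], bounds.upper[1])
            k_hi = lp + p2 * bounds.v_hi
            if math.log(bounds.k_min) <= k_hi <= math.log(bounds.k_max):
                ref.append(lp)
        assert ks_2samp(log_p1, np.asarray(ref)).pvalue > 1e-3


class TestRunFit:
    def test_sphere_in_nine_dimensions(self, bounds, transform):
        lo_t, hi_t = transform.bounds_in_search_space(bounds)
        target = transform.to_search(
            ModelParameters(1e-3, 0.05, 1e-3, 0.05, 0.05, 0.01, 0.01, 0.03, 0.1)
        )
        scaled_target = (target - lo_t) / (hi_t - lo_t)

        def objective(p: ModelParameters) -> float:
            u = (transform.to_search(p) - lo_t) / (hi_t - lo_t)
            return float(np.sum((u - scaled_target) ** 2))

        config = OptimizerConfig(ftol=1e-13, stall_iters=60, max_iters=2000)
        result = run_fit(objective, bounds, transform, config, seed=3)
        assert result.score < 1e-6
        assert result.converged

    def test_seeded_determinism(self, bounds, transform):
        def objective(p: ModelParameters) -> float:
            x = np.log(p.as_array())
            return float(np.sum((x - np.mean(x)) ** 2))

        config = OptimizerConfig(ftol=1e-9, stall_iters=20, max_iters=60)
        a = run_fit(objective, bounds, transform, config, seed=11)
        b = run_fit(objective, bounds, transform, config, seed=11)
        assert a.score == b.score
        assert a.params == b.params
        assert a.n_evaluations == b.n_evaluations

    def test_recovers_noiseless_sine_protocol_truth(self, protocols, params,
                                                    conditions):
        """On noiseless data the whole-trace objective has its optimum at the
        generating parameters; a single run should land within 1%."""
        from ikrfit.objectives import make_e_m4_objective
        from ikrfit.synthetic import SyntheticSpec, generate_cell

        spec = SyntheticSpec(
            true_params=params, conditions=conditions, seed=0,
            noise_sigma=0.0, include=("Pr7",),
        )
        cell = generate_cell(spec, protocols=protocols, dt={"Pr7": 0.5})
        objective = make_e_m4_objective(cell, protocols["Pr7"])
        config = OptimizerConfig(ftol=1e-11, stall_iters=60, max_iters=1500)
        result = run_fit(objective, bounds=default_bounds(),
                         transform=SearchTransform.default(),
                         config=config, seed=21)
        assert result.score < 1e-4
        rel = np.abs(result.params.as_array() / params.as_array() - 1.0)
        assert np.max(rel) < 0.01


class TestMultiStart:
    @staticmethod
    def _quadratic(p: ModelParameters) -> float:
        x = np.log(p.as_array())
        return float(np.sum((x + 2.0) ** 2))

    def test_best_is_minimum(self, bounds, transform):
        config = OptimizerConfig(ftol=1e-9, stall_iters=10, max_iters=40)
        results, best = multi_start(
            self._quadratic, bounds, transform, config, n_repeats=4, seed=2
        )
        assert len(results) == 4
        assert best.score == min(r.score for r in results)

    def test_single_repeat(self, bounds, transform):
        config = OptimizerConfig(ftol=1e-9, stall_iters=10, max_iters=30)
        results, best = multi_start(
            self._quadratic, bounds, transform, config, n_repeats=1, seed=2
        )
        assert len(results) == 1
        assert best.score == results[0].score


def _result(score, theta):
    return FitResult(
        params=ModelParameters.from_array(theta), score=score, method="t",
        seed=0, start=None, n_evaluations=1, n_iterations=1, converged=True,
    )


class TestReliability:
    def test_identical_results(self):
        theta = np.full(9, 0.5)
        results = [_result(1.0, theta) for _ in range(5)]
        assert reliability(results) == (1.0, 1.0)

    def test_hand_computed_fractions(self):
        base = np.full(9, 0.5)
        far = base.copy()
        far[3] *= 1.5
        results = [
            _result(1.000, base),   # best
            _result(1.005, base),   # close in score and parameters
            _result(1.005, far),    # close in score, far in parameters
            _result(2.000, base),   # far in score
        ]
        frac_rmse, frac_param = reliability(results)
        assert frac_rmse == pytest.approx(3 / 4)
        assert frac_param == pytest.approx(2 / 4)

    def test_nesting_property(self, rng):
        for _ in range(20):
            results = [
                _result(
                    1.0 + abs(rng.normal(0, 0.02)),
                    np.full(9, 0.5) * (1.0 + rng.normal(0, 0.02, 9)),
                )
                for _ in range(8)
            ]
            frac_rmse, frac_param = reliability(results)
            assert frac_param <= frac_rmse

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reliability([])


class TestSeededStart:
    def test_feasible_point_unchanged(self, params, bounds, transform):
        x = seeded_start_from_method1(params, bounds, transform)
        assert np.allclose(
            transform.from_search(x), params.as_array(), rtol=1e-12
        )

    def test_box_violation_clipped(self, params, bounds, transform):
        wild = ModelParameters.from_array(
            np.concatenate([params.as_array()[:8], [1e9]])
        )
        x = seeded_start_from_method1(wild, bounds, transform)
        theta = transform.from_search(x)
        assert theta[8] == pytest.approx(bounds.upper[8])
        assert in_bounds(theta, bounds)

    def test_rate_violation_projected_onto_band(self, bounds, transform):
        theta = np.array([900.0, 0.35, 3.45e-5, 0.05, 0.0873, 0.0089,
                          5.15e-3, 0.0316, 0.1524])
        assert not in_bounds(theta, bounds)
        x = seeded_start_from_method1(
            ModelParameters.from_array(theta), bounds, transform
        )
        assert in_bounds(transform.from_search(x), bounds)
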