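"""Constrained, transformed, multi-start global optimization.

The search space is the parameter box intersected with rate constraints
(each transition rate restricted to physiological timescales over the
relevant voltage range); points outside are scored ``inf``.  Searching is
done in a log-transformed space for the rate pre-factors (and, by default,
the conductance), scaled to the unit box.  The optimizer is CMA-ES with a
population of 10 and a stall-based stopping rule; reliability of a fit is
assessed by running repeats from independently sampled start points and
counting how many land near the best result.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from ._cmaes import cmaes_minimize
from .model import ModelParameters

__all__ = [
    "ParameterBounds",
    "SearchTransform",
    "OptimizerConfig",
    "FitResult",
    "default_bounds",
    "in_bounds",
    "sample_start_points",
    "run_fit",
    "multi_start",
    "reliability",
    "seeded_start_from_method1",
]

logger = logging.getLogger(__name__)

PARAM_ORDER = ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9")


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds plus rate constraints.

    Each rate is monotone in voltage, so constraining it at the voltage
    extreme where it attains its maximum (``v_hi`` for the rates that grow
    with V, ``v_lo`` for those that shrink) confines the corresponding
    (log prefactor, sensitivity) pair to a band between two parallel lines.
    """

    lower: np.ndarray
    upper: np.ndarray
    k_min: float
    k_max: float
    v_lo: float
    v_hi: float

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (9,) or hi.shape != (9,):
            raise ValueError("bounds must have 9 entries")
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be below upper bounds")
        if self.k_min <= 0 or self.k_max <= self.k_min:
            raise ValueError("need 0 < k_min < k_max")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def rate_exponent_voltage(self, which: int) -> float:
        """Voltage at which rate ``which`` (1..4) is largest."""
        return self.v_hi if which in (1, 3) else self.v_lo


def default_bounds() -> ParameterBounds:
    """Load the packaged default bounds."""
    from importlib import resources

    with resources.files("ikrfit.data").joinpath("bounds.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return ParameterBounds(
        lower=np.array([cfg["lower"][p] for p in PARAM_ORDER]),
        upper=np.array([cfg["upper"][p] for p in PARAM_ORDER]),
        k_min=float(cfg["rates"]["k_min"]),
        k_max=float(cfg["rates"]["k_max"]),
        v_lo=float(cfg["rates"]["v_lo"]),
        v_hi=float(cfg["rates"]["v_hi"]),
    )


def _rate_logs(theta: np.ndarray, bounds: ParameterBounds) -> np.ndarray:
    """log of each rate at its maximizing voltage extreme."""
    return np.array(
        [
            math.log(theta[0]) + theta[1] * bounds.v_hi,   # k1 at v_hi
            math.log(theta[2]) - theta[3] * bounds.v_lo,   # k2 at v_lo
            math.log(theta[4]) + theta[5] * bounds.v_hi,   # k3 at v_hi
            math.log(theta[6]) - theta[7] * bounds.v_lo,   # k4 at v_lo
        ]
    )


def in_bounds(params, bounds: ParameterBounds) -> bool:
    """True iff the box bounds and all rate constraints are satisfied."""
    theta = params.as_array() if isinstance(params, ModelParameters) else np.asarray(params, float)
    if np.any(theta < bounds.lower) or np.any(theta > bounds.upper):
        return False
    logs = _rate_logs(theta, bounds)
    return bool(
        np.all(logs >= math.log(bounds.k_min)) and np.all(logs <= math.log(bounds.k_max))
    )


@dataclass(frozen=True)
class SearchTransform:
    """Per-parameter choice of log or identity search coordinates."""

    log_mask: Tuple[bool, ...]

    @classmethod
    def default(cls, log_conductance: bool = True) -> "SearchTransform":
        """Log transform on the rate pre-factors p1, p3, p5, p7; the
        conductance also spans decades, so it is searched in log space by
        default (flag-controlled)."""
        mask = [True, False, True, False, True, False, True, False, log_conductance]
        return cls(log_mask=tuple(mask))

    @classmethod
    def identity(cls) -> "SearchTransform":
        return cls(log_mask=(False,) * 9)

    def to_search(self, params) -> np.ndarray:
        theta = (
            params.as_array() if isinstance(params, ModelParameters)
            else np.asarray(params, float)
        )
        x = theta.copy()
        mask = np.asarray(self.log_mask)
        if np.any(theta[mask] <= 0):
            raise ValueError("log transform requires strictly positive values")
        x[mask] = np.log(theta[mask])
        return x

    def from_search(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        theta = x.copy()
        mask = np.asarray(self.log_mask)
        theta[mask] = np.exp(x[mask])
        return theta

    def bounds_in_search_space(self, bounds: ParameterBounds):
        return self.to_search(bounds.lower), self.to_search(bounds.upper)


@dataclass
class OptimizerConfig:
    """CMA-ES configuration; the defaults mirror the strategy used for the
    full-size fits (population 10, stop after the objective changes by less
    than 1e-11 per iteration for 200 successive iterations)."""

    pop_size: int = 10
    ftol: float = 1e-11
    stall_iters: int = 200
    max_iters: int = 10_000
    sigma0_frac: float = 1.0 / 6.0


@dataclass
class FitResult:
    """One optimization repeat."""

    params: ModelParameters
    score: float
    method: str
    seed: int
    start: Optional[ModelParameters]
    n_evaluations: int
    n_iterations: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "score": self.score,
            "method": self.method,
            "seed": self.seed,
            "start": None if self.start is None else self.start.to_dict(),
            "n_evaluations": self.n_evaluations,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            params=ModelParameters.from_dict(d["params"]),
            score=float(d["score"]),
            method=d["method"],
            seed=int(d["seed"]),
            start=(
                None if d.get("start") is None
                else ModelParameters.from_dict(d["start"])
            ),
            n_evaluations=int(d["n_evaluations"]),
            n_iterations=int(d["n_iterations"]),
            converged=bool(d["converged"]),
        )


def sample_start_points(
    n: int,
    bounds: ParameterBounds,
    transform: SearchTransform,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """n start points, uniform in the transformed box and rejection-sampled
    to satisfy the rate constraints.  Returned in search-space coordinates."""
    lo, hi = transform.bounds_in_search_space(bounds)
    points: List[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("start-point sampling: acceptance rate too low")
        batch = rng.uniform(lo, hi, size=(max(64, 4 * n), 9))
        for x in batch:
            if in_bounds(transform.from_search(x), bounds):
                points.append(x)
                if len(points) == n:
                    break
    return points


#: Finite stand-in for the infinite error assigned outside the feasible
#: region: large enough to rank behind any real objective value, graded by
#: the constraint violation so the search is pulled back towards
#: feasibility instead of drifting.
PENALTY_BASE = 1e10


def _violation(u: np.ndarray, theta: np.ndarray, bounds: ParameterBounds) -> float:
    """Zero inside the feasible region, growing with distance outside."""
    v = float(np.sum(np.maximum(u - 1.0, 0.0) + np.maximum(-u, 0.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        if np.all(theta > 0):
            logs = _rate_logs(theta, bounds)
            v += float(
                np.sum(np.maximum(logs - math.log(bounds.k_max), 0.0))
                + np.sum(np.maximum(math.log(bounds.k_min) - logs, 0.0))
            )
    return v


def _penalized(
    objective: Callable[[ModelParameters], float],
    bounds: ParameterBounds,
    transform: SearchTransform,
    lo_t: np.ndarray,
    span_t: np.ndarray,
):
    """Objective over the unit-scaled search space.  Points outside the
    feasible region carry an effectively infinite error; inside the
    optimizer this is represented by a large violation-graded penalty so
    that selection still ranks them sensibly."""

    def wrapped(u: np.ndarray) -> float:
        x = lo_t + u * span_t
        theta = transform.from_search(x)
        if not in_bounds(theta, bounds):
            return PENALTY_BASE * (1.0 + _violation(u, theta, bounds))
        try:
            value = objective(ModelParameters.from_array(theta))
        except Exception as exc:  # simulation/derivation failures
            logger.debug("objective failure: %s", exc)
            return PENALTY_BASE
        return value if np.isfinite(value) else PENALTY_BASE

    return wrapped


def run_fit(
    objective: Callable[[ModelParameters], float],
    bounds: ParameterBounds,
    transform: SearchTransform,
    config: OptimizerConfig,
    seed: int = 0,
    x0: Optional[np.ndarray] = None,
    method: str = "custom",
) -> FitResult:
    """One CMA-ES run.  ``x0`` is a search-space start point; when omitted
    one is sampled uniformly from the feasible transformed box."""
    rng = np.random.default_rng(seed)
    lo_t, hi_t = transform.bounds_in_search_space(bounds)
    span_t = hi_t - lo_t
    if x0 is None:
        x0 = sample_start_points(1, bounds, transform, rng)[0]
    u0 = (np.asarray(x0, float) - lo_t) / span_t
    start_params = ModelParameters.from_array(transform.from_search(x0))

    wrapped = _penalized(objective, bounds, transform, lo_t, span_t)
    result = cmaes_minimize(
        wrapped,
        u0,
        sigma0=config.sigma0_frac,
        rng=rng,
        popsize=config.pop_size,
        max_iter=config.max_iters,
        ftol=config.ftol,
        stall_iters=config.stall_iters,
    )
    if result.fun < PENALTY_BASE:
        best = ModelParameters.from_array(
            transform.from_search(lo_t + result.x * span_t)
        )
        converged = result.converged
        score = float(result.fun)
    else:
        # never left the infeasible region: report an infinite error
        best = start_params
        converged = False
        score = np.inf
    return FitResult(
        params=best,
        score=score,
        method=method,
        seed=seed,
        start=start_params,
        n_evaluations=result.n_evaluations,
        n_iterations=result.n_iterations,
        converged=converged,
    )


def multi_start(
    objective: Callable[[ModelParameters], float],
    bounds: ParameterBounds,
    transform: SearchTransform,
    config: OptimizerConfig,
    n_repeats: int,
    seed: int = 0,
    method: str = "custom",
    starts: Optional[Sequence[np.ndarray]] = None,
    polish: Optional[OptimizerConfig] = None,
) -> Tuple[List[FitResult], FitResult]:
    """Independent seeded repeats; the best (lowest score, first
    encountered on ties) is the final fit.

    When ``polish`` is given, one extra local run (small initial step)
    restarts from the best repeat and replaces it if it improves — useful
    in budgeted runs where the per-repeat iteration count is capped.
    """
    children = np.random.SeedSequence(seed).spawn(n_repeats + 1)
    results = []
    for i, child in enumerate(children[:n_repeats]):
        repeat_seed = int(child.generate_state(1)[0])
        x0 = None if starts is None else starts[i]
        result = run_fit(
            objective, bounds, transform, config,
            seed=repeat_seed, x0=x0, method=method,
        )
        logger.info(
            "%s repeat %d/%d: score=%.6g evals=%d converged=%s",
            method, i + 1, n_repeats, result.score,
            result.n_evaluations, result.converged,
        )
        results.append(result)
    best = min(results, key=lambda r: r.score)
    if polish is not None and np.isfinite(best.score):
        refined = run_fit(
            objective, bounds, transform, polish,
            seed=int(children[-1].generate_state(1)[0]),
            x0=transform.to_search(best.params),
            method=method,
        )
        if refined.score < best.score:
            best = refined
    return results, best


def reliability(
    results: Sequence[FitResult],
    rmse_tol: float = 0.01,
    param_tol: float = 0.01,
) -> Tuple[float, float]:
    """Fractions of repeats near the best result.

    Returns ``(frac_rmse_close, frac_param_close)``: the fraction whose
    score is within ``rmse_tol`` (relative) of the best score, and the
    fraction that additionally has every parameter within ``param_tol``
    (relative) of the best parameters.  The second condition nests inside
    the first, so ``frac_param_close <= frac_rmse_close`` always.
    """
    if not results:
        raise ValueError("need at least one result")
    best = min(results, key=lambda r: r.score)
    best_theta = best.params.as_array()
    n_rmse = 0
    n_param = 0
    for r in results:
        close_rmse = r.score <= best.score * (1 + rmse_tol) + 1e-300
        if close_rmse:
            n_rmse += 1
            rel = np.abs(r.params.as_array() - best_theta) / np.abs(best_theta)
            if np.all(rel <= param_tol):
                n_param += 1
    return n_rmse / len(results), n_param / len(results)


def seeded_start_from_method1(
    params: ModelParameters,
    bounds: ParameterBounds,
    transform: SearchTransform,
) -> np.ndarray:
    """Project a direct-fit result into the feasible region, in search
    coordinates: clip to the box, then pull each rate pre-factor onto the
    nearest point of its rate band if needed."""
    theta = np.clip(params.as_array(), bounds.lower, bounds.upper)
    log_kmin, log_kmax = math.log(bounds.k_min), math.log(bounds.k_max)
    pairs = ((0, 1, bounds.v_hi), (2, 3, -bounds.v_lo),
             (4, 5, bounds.v_hi), (6, 7, -bounds.v_lo))
    for i_pre, i_sens, v in pairs:
        log_k = math.log(theta[i_pre]) + theta[i_sens] * v
        log_pre = math.log(theta[i_pre]) + np.clip(log_k, log_kmin, log_kmax) - log_k
        theta[i_pre] = np.clip(
            math.exp(log_pre), bounds.lower[i_pre], bounds.upper[i_pre]
        )
    return transform.to_search(theta)


def save_results(results: Sequence[FitResult], path: Union[str, Path], extra=None):
    payload = {"results": [r.to_dict() for r in results]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_results(path: Union[str, Path]) -> List[FitResult]:
    payload = json.loads(Path(path).read_text())
    return [FitResult.from_dict(d) for d in payload["results"]]
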