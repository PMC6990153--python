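"""Direct, simulation-free fit of the model to a set of summary curves.

Both steady-state curves are algebraically sigmoids in the voltage,
``1 / (1 + exp(s (h - V)))``, so a two-parameter fit of each yields two
constraints per gate.  The ratio steady-state/time-constant equals a single
Eyring rate (``a_inf / tau_a = k1``), so a log-linear regression of that
ratio against voltage yields the remaining two parameters per gate by
back-substitution.  Only the conductance requires a simulation: one run of
the Pr5 protocol, after which the optimal scaling of the IV curve is a
closed-form linear least squares.

The whole procedure is deterministic: applied twice to the same summary
set it returns bit-identical parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .model import IonicConditions, ModelParameters
from .protocols import Protocol
from .summarize import Curve, SummarySet, analyse_pr5

__all__ = [
    "BoltzmannFit",
    "Method1Error",
    "fit_boltzmann",
    "activation_rates_from_summary",
    "inactivation_rates_from_summary",
    "conductance_from_iv",
    "method1_fit",
    "method1_numeric",
]


class Method1Error(RuntimeError):
    """Degenerate input or a positivity violation during back-substitution."""


@dataclass(frozen=True)
class BoltzmannFit:
    """Sigmoid ``1 / (1 + exp(s (h - V)))``; s > 0 rises with voltage."""

    h: float
    s: float

    def __call__(self, V):
        return 1.0 / (1.0 + np.exp(self.s * (self.h - np.asarray(V, float))))


def fit_boltzmann(points: Curve, direction: str) -> BoltzmannFit:
    """Least-squares sigmoid fit of a steady-state curve.

    ``direction`` is ``"increasing"`` (activation, s > 0) or
    ``"decreasing"`` (inactivation, s < 0).
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    V = np.asarray(points.voltages, float)
    y = np.asarray(points.values, float)
    if V.size < 3:
        raise Method1Error("need at least 3 points for a Boltzmann fit")
    if np.ptp(y) < 1e-12:
        raise Method1Error("degenerate steady-state data (flat)")

    sign = 1.0 if direction == "increasing" else -1.0

    # Midpoint guess: crossing of 0.5; slope guess from a logit regression.
    yc = np.clip(y, 1e-6, 1.0 - 1e-6)
    logit = np.log(yc / (1.0 - yc))
    slope, intercept = np.polyfit(V, logit, 1)
    s0 = sign * max(abs(slope), 1e-4)
    h0 = -intercept / slope if abs(slope) > 1e-12 else float(np.mean(V))

    def residuals(x):
        h, log_s = x
        s = sign * math.exp(log_s)
        return 1.0 / (1.0 + np.exp(np.clip(s * (h - V), -500, 500))) - y

    res = least_squares(
        residuals,
        np.array([h0, math.log(abs(s0))]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    h, s = float(res.x[0]), sign * math.exp(float(res.x[1]))
    return BoltzmannFit(h=h, s=s)


def _rate_regression(voltages: np.ndarray, log_rates: np.ndarray):
    """Ordinary least squares of log-rate against voltage."""
    slope, intercept = np.polyfit(voltages, log_rates, 1)
    return float(slope), float(intercept)


def activation_rates_from_summary(
    boltz: BoltzmannFit, tau_act: Curve
) -> Tuple[float, float, float, float]:
    """Recover (p1, p2, p3, p4) from the activation Boltzmann fit and the
    activation time constants.

    ``a_inf(V) / tau_a(V) = k1 = p1 exp(p2 V)``; the fitted Boltzmann is
    used for ``a_inf`` (not the measured points) to reduce noise, and the
    regression is done on the logarithm.  Back-substitution then gives
    ``p4 = s_a - p2`` and ``p3 = p1 exp(s_a h_a)``.
    """
    if boltz.s <= 0:
        raise Method1Error("activation Boltzmann must be increasing (s > 0)")
    if len(tau_act) < 2:
        raise Method1Error("need at least 2 activation time constants")
    V = tau_act.voltages
    a_inf = boltz(V)
    log_k1 = np.log(a_inf / tau_act.values)
    p2, log_p1 = _rate_regression(V, log_k1)
    p1 = math.exp(log_p1)
    p4 = boltz.s - p2
    p3 = p1 * math.exp(boltz.s * boltz.h)
    if p2 <= 0 or p4 <= 0 or p3 <= 0:
        raise Method1Error(
            f"positivity violation in activation back-substitution: "
            f"p1={p1:.3g} p2={p2:.3g} p3={p3:.3g} p4={p4:.3g}"
        )
    return p1, p2, p3, p4


def inactivation_rates_from_summary(
    boltz: BoltzmannFit, tau_inact: Curve
) -> Tuple[float, float, float, float]:
    """Recover (p5, p6, p7, p8) — as for activation but with the signs of a
    decreasing sigmoid: regress ``log(r_inf / tau_r) = log k4 = log p7 - p8 V``,
    then ``p6 = -s_r - p8`` and ``p5 = p7 exp(s_r h_r)``."""
    if boltz.s >= 0:
        raise Method1Error("inactivation Boltzmann must be decreasing (s < 0)")
    if len(tau_inact) < 2:
        raise Method1Error("need at least 2 inactivation time constants")
    V = tau_inact.voltages
    r_inf = boltz(V)
    log_k4 = np.log(r_inf / tau_inact.values)
    neg_p8, log_p7 = _rate_regression(V, log_k4)
    p8 = -neg_p8
    p7 = math.exp(log_p7)
    p6 = -boltz.s - p8
    p5 = p7 * math.exp(boltz.s * boltz.h)
    if p8 <= 0 or p6 <= 0 or p5 <= 0:
        raise Method1Error(
            f"positivity violation in inactivation back-substitution: "
            f"p5={p5:.3g} p6={p6:.3g} p7={p7:.3g} p8={p8:.3g}"
        )
    return p5, p6, p7, p8


def conductance_from_iv(
    kinetics,
    iv_cell: Curve,
    protocol_pr5: Protocol,
    conditions: IonicConditions,
    dt: Optional[float] = None,
) -> float:
    """Conductance by closed-form scaling of a unit-conductance IV curve.

    The simulated IV curve is proportional to the conductance, so the
    scaling factor minimizing the sum-of-squares error is
    ``(IV_sim . IV_cell) / (IV_sim . IV_sim)``.
    """
    from .simulate import simulate_step

    unit = ModelParameters(*kinetics, 1.0)
    traces = simulate_step(unit, protocol_pr5, conditions, dt)
    iv_sim = analyse_pr5(traces, protocol_pr5, conditions.E_K)["iv"]
    x = iv_sim.values
    y = np.asarray(iv_cell.values, float)
    denom = float(x @ x)
    if denom <= 0:
        raise Method1Error("simulated IV curve is identically zero")
    p9 = float(x @ y) / denom
    if p9 <= 0:
        raise Method1Error(f"non-positive conductance estimate {p9:.3g}")
    return p9


def method1_fit(
    summary: SummarySet,
    protocol_pr5: Protocol,
    conditions: IonicConditions,
    dt: Optional[float] = None,
) -> ModelParameters:
    """The full direct fit: Boltzmann fits, log-linear rate regressions,
    back-substitution, and one simulation for the conductance."""
    act = fit_boltzmann(summary.act_ss, "increasing")
    inact = fit_boltzmann(summary.inact_ss, "decreasing")
    p1, p2, p3, p4 = activation_rates_from_summary(act, summary.tau_act)
    p5, p6, p7, p8 = inactivation_rates_from_summary(inact, summary.tau_inact)
    p9 = conductance_from_iv(
        (p1, p2, p3, p4, p5, p6, p7, p8), summary.iv, protocol_pr5, conditions, dt
    )
    return ModelParameters(p1, p2, p3, p4, p5, p6, p7, p8, p9)


def method1_numeric(
    summary: SummarySet,
    protocol_pr5: Protocol,
    conditions: IonicConditions,
    bounds=None,
    n_repeats: int = 5,
    seed: int = 0,
    dt: Optional[float] = None,
    fit_config=None,
):
    """Alternative mode: numerically minimize the summary-curve error over
    the eight kinetic parameters, then estimate the conductance as in the
    direct method.  The error measure is conductance-invariant, so p9 is
    not searched."""
    from .objectives import e_m1_curves
    from .optimize import (
        OptimizerConfig,
        SearchTransform,
        default_bounds,
        multi_start,
    )

    bounds = bounds if bounds is not None else default_bounds()
    transform = SearchTransform.default()
    config = fit_config if fit_config is not None else OptimizerConfig()

    def objective(params: ModelParameters) -> float:
        return e_m1_curves(params, summary)

    results, best = multi_start(
        objective, bounds, transform, config, n_repeats=n_repeats, seed=seed,
        method="1-numeric",
    )
    kin = best.params.kinetics()
    p9 = conductance_from_iv(kin, summary.iv, protocol_pr5, conditions, dt)
    return ModelParameters(*kin, p9), results
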