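"""Two-gate Hodgkin-Huxley model of the rapid delayed-rectifier current IKr.

The current is ``I = p9 * a * r * (V - E_K)`` where the activation gate ``a``
and the recovery (from inactivation) gate ``r`` each relax exponentially
towards a voltage-dependent steady state.  All four transition rates follow
an Eyring-style exponential voltage dependence.

Units used throughout the package: time in milliseconds, voltage in
millivolts, rates in 1/ms, voltage sensitivities in 1/mV.  The current unit
is inherited from the conductance ``p9`` (nanoamps when ``p9`` is in
microsiemens).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY_CONSTANT",
    "ModelParameters",
    "RateSet",
    "GateSummary",
    "GateState",
    "IonicConditions",
    "ModelEvaluationError",
    "transition_rates",
    "gate_summary",
    "nernst",
    "current",
    "ode_rhs",
    "analytic_step_solution",
    "steady_state",
]

#: Molar gas constant, J / (K mol)  (CODATA 2018)
GAS_CONSTANT = 8.314462618
#: Faraday constant, C / mol  (CODATA 2018)
FARADAY_CONSTANT = 96485.33212

#: Largest |exponent| accepted when evaluating the rate equations.  Beyond
#: this the result would overflow double precision; the evaluation is then
#: reported as invalid so that objective functions can map it to infinity
#: instead of propagating NaN/inf.
MAX_RATE_EXPONENT = 700.0

PARAM_NAMES = ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9")


class ModelEvaluationError(ValueError):
    """Raised when a model evaluation is numerically invalid (overflow)."""


@dataclass(frozen=True)
class ModelParameters:
    """The nine strictly positive model parameters.

    ``p1, p3, p5, p7`` are rate pre-factors (1/ms); ``p2, p4, p6, p8`` are
    voltage sensitivities (1/mV); ``p9`` is the maximal conductance.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float
    p9: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"parameter {name} must be strictly positive and finite, "
                    f"got {value!r}"
                )

    # -- conversions -----------------------------------------------------

    def as_array(self) -> np.ndarray:
        """Return the parameters as a length-9 float array (p1..p9)."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "ModelParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (9,):
            raise ValueError(f"expected 9 parameters, got shape {values.shape}")
        return cls(*values.tolist())

    def kinetics(self) -> np.ndarray:
        """Return the eight kinetic parameters p1..p8 as an array."""
        return self.as_array()[:8]

    def with_conductance(self, p9: float) -> "ModelParameters":
        return ModelParameters(*self.as_array()[:8].tolist(), p9)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ModelParameters":
        text = Path(path).read_text()
        if "=" in text.splitlines()[0] and not text.lstrip().startswith("{"):
            d = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                d[key.strip()] = float(value)
            return cls.from_dict(d)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class RateSet:
    """Transition rates (1/ms) of the two gating reactions at one voltage."""

    k1: float
    k2: float
    k3: float
    k4: float


@dataclass(frozen=True)
class GateSummary:
    """Steady states and time constants of both gates at one voltage."""

    a_inf: float
    r_inf: float
    tau_a: float
    tau_r: float


@dataclass(frozen=True)
class GateState:
    """Instantaneous gate occupancies, with the time they refer to (ms)."""

    a: float
    r: float
    t: float = 0.0


@dataclass(frozen=True)
class IonicConditions:
    """Potassium concentrations (mM), temperature (K) and the implied E_K.

    ``E_K`` is computed from the Nernst equation on construction; the
    concentrations are configuration, not hard-coded constants, because the
    experimental values live with the recordings themselves.
    """

    K_out: float
    K_in: float
    T: float
    E_K: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "E_K", nernst(self.K_out, self.K_in, self.T))


def nernst(K_out: float, K_in: float, T: float) -> float:
    """Potassium reversal potential (mV) for a monovalent ion.

    ``E_K = (R T / F) ln([K+]_o / [K+]_i)`` with R, T in SI units; the result
    is converted to millivolts.
    """
    if K_out <= 0 or K_in <= 0 or T <= 0:
        raise ValueError("concentrations and temperature must be positive")
    return 1e3 * GAS_CONSTANT * T / FARADAY_CONSTANT * math.log(K_out / K_in)


def transition_rates(params: ModelParameters, V: float) -> RateSet:
    """Evaluate the four Eyring-exponential transition rates at voltage V.

    ``k1 = p1 exp(p2 V)``, ``k2 = p3 exp(-p4 V)``, ``k3 = p5 exp(p6 V)``,
    ``k4 = p7 exp(-p8 V)``.

    Raises :class:`ModelEvaluationError` if any exponent would overflow.
    """
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    exponents = (params.p2 * V, -params.p4 * V, params.p6 * V, -params.p8 * V)
    if max(abs(e) for e in exponents) > MAX_RATE_EXPONENT:
        raise ModelEvaluationError(
            f"rate exponent overflow at V={V} mV; evaluation is invalid"
        )
    return RateSet(
        k1=params.p1 * math.exp(exponents[0]),
        k2=params.p3 * math.exp(exponents[1]),
        k3=params.p5 * math.exp(exponents[2]),
        k4=params.p7 * math.exp(exponents[3]),
    )


def gate_summary(params: ModelParameters, V: float) -> GateSummary:
    """Steady states and time constants at voltage V.

    ``tau_a = 1/(k1+k2)``, ``a_inf = k1 tau_a`` and analogously for the
    recovery gate (``tau_r = 1/(k3+k4)``, ``r_inf = k4 tau_r``).
    """
    k = transition_rates(params, V)
    tau_a = 1.0 / (k.k1 + k.k2)
    tau_r = 1.0 / (k.k3 + k.k4)
    return GateSummary(
        a_inf=k.k1 * tau_a, r_inf=k.k4 * tau_r, tau_a=tau_a, tau_r=tau_r
    )


def summary_curves(params: ModelParameters, voltages) -> dict:
    """Vectorized :func:`gate_summary` over an array of voltages.

    Returns a dict with arrays ``a_inf``, ``r_inf``, ``tau_a``, ``tau_r``.
    """
    V = np.asarray(voltages, dtype=float)
    exps = np.array([params.p2, -params.p4, params.p6, -params.p8])
    E = np.outer(exps, V)
    if np.max(np.abs(E)) > MAX_RATE_EXPONENT:
        raise ModelEvaluationError("rate exponent overflow")
    pre = np.array([params.p1, params.p3, params.p5, params.p7])
    k = pre[:, None] * np.exp(E)
    tau_a = 1.0 / (k[0] + k[1])
    tau_r = 1.0 / (k[2] + k[3])
    return {
        "a_inf": k[0] * tau_a,
        "r_inf": k[3] * tau_r,
        "tau_a": tau_a,
        "tau_r": tau_r,
    }


def current(
    params: ModelParameters, state: GateState, V: float, E_K: float
) -> float:
    """Ohmic current ``p9 * a * r * (V - E_K)``."""
    return params.p9 * state.a * state.r * (V - E_K)


def ode_rhs(params: ModelParameters, V: float, state: GateState):
    """Right-hand side ``(da/dt, dr/dt)`` of the gating ODEs at voltage V."""
    s = gate_summary(params, V)
    return (
        (s.a_inf - state.a) / s.tau_a,
        (s.r_inf - state.r) / s.tau_r,
    )


def analytic_step_solution(
    params: ModelParameters, V: float, initial: GateState, t: float
) -> GateState:
    """Exact gate state after holding voltage V for a duration t (ms).

    At fixed voltage each gate relaxes as a single exponential,
    ``a(t) = a_inf + (a0 - a_inf) exp(-t / tau_a)``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return initial
    s = gate_summary(params, V)
    a = s.a_inf + (initial.a - s.a_inf) * math.exp(-t / s.tau_a)
    r = s.r_inf + (initial.r - s.r_inf) * math.exp(-t / s.tau_r)
    return GateState(a=a, r=r, t=initial.t + t)


def steady_state(params: ModelParameters, V: float) -> GateState:
    """Gate state at the fixed point for voltage V."""
    s = gate_summary(params, V)
    return GateState(a=s.a_inf, r=s.r_inf, t=0.0)
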