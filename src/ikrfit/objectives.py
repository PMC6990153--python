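"""Scalar error measures linking a parameter set to a cell's data.

Five measures are provided: a conductance-invariant comparison of model
curves to the summary curves (no simulation), a comparison of *simulated*
summary curves to the experimental ones, whole-trace errors on the step
protocols and on the short sinusoidal protocol, and a validation error on
the action-potential waveform protocol.  All are weighted sums of RMSEs
with cell-specific normalizations so that values are comparable between
cells; all are non-negative; failures of simulation or of the embedded
summary derivation map to ``inf`` so optimizers treat those regions as
infeasible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import _core
from .model import IonicConditions, ModelEvaluationError, ModelParameters, summary_curves
from .protocols import Protocol
from .simulate import SimulationError, Trace, simulate_ode, simulate_step
from .summarize import SummaryError, SummarySet, assemble_summary

__all__ = [
    "CellDataset",
    "rmse",
    "e_m1",
    "e_m1_curves",
    "e_m2",
    "e_m3",
    "e_m4",
    "e_ap",
    "e_all",
]

logger = logging.getLogger(__name__)

STEP_PROTOCOLS = ("Pr2", "Pr3", "Pr4", "Pr5")


@dataclass
class CellDataset:
    """Everything recorded (or synthesized) for one cell."""

    cell_id: str
    traces: Dict[str, List[Trace]]
    summary: Optional[SummarySet]
    conditions: IonicConditions
    meta: dict = field(default_factory=dict)

    def has(self, protocol: str) -> bool:
        return protocol in self.traces


def rmse(x, y) -> float:
    """Root mean-squared error between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    d = x - y
    return float(np.sqrt(np.mean(d * d)))


def e_m1_curves(params: ModelParameters, summary: SummarySet) -> float:
    """Summary-curve error against the *model* curves (no simulation).

    ``R(act) + R(inact) + R(tau_a)/max(tau_a_cell) + R(tau_r)/max(tau_r_cell)``
    with the model variables evaluated analytically at the summary voltages.
    Invariant under any change of the conductance.
    """
    try:
        act = summary_curves(params, summary.act_ss.voltages)["a_inf"]
        inact = summary_curves(params, summary.inact_ss.voltages)["r_inf"]
        tau_a = summary_curves(params, summary.tau_act.voltages)["tau_a"]
        tau_r = summary_curves(params, summary.tau_inact.voltages)["tau_r"]
    except ModelEvaluationError:
        return np.inf
    return (
        rmse(summary.act_ss.values, act)
        + rmse(summary.inact_ss.values, inact)
        + rmse(summary.tau_act.values, tau_a) / np.max(summary.tau_act.values)
        + rmse(summary.tau_inact.values, tau_r) / np.max(summary.tau_inact.values)
    )


def e_m1(params: ModelParameters, cell: CellDataset) -> float:
    if cell.summary is None:
        raise ValueError("cell has no summary curves")
    return e_m1_curves(params, cell.summary)


def _aligned(sim_curve, cell_curve):
    """Simulated curve values at the cell curve's voltages (or None)."""
    lookup = {round(v, 6): y for v, y in zip(sim_curve.voltages, sim_curve.values)}
    out = []
    for v in cell_curve.voltages:
        key = round(float(v), 6)
        if key not in lookup:
            return None
        out.append(lookup[key])
    return np.asarray(out)


def e_m2(
    params: ModelParameters,
    cell: CellDataset,
    protocols: Dict[str, Protocol],
    dt: Optional[float] = None,
) -> float:
    """Simulated-summary-curve error.

    The step protocols are simulated and passed through the identical
    extraction pipeline used on the experimental data; the error compares
    the activation curve, both time-constant curves, and the IV curve (42
    points on the default protocols).  The IV curve replaces the steady
    state of inactivation: same information, no near-reversal numerical
    trouble, and it carries the conductance.  Any derivation failure yields
    ``inf``.
    """
    summary = cell.summary
    if summary is None:
        raise ValueError("cell has no summary curves")
    if dt is None and cell.has("Pr2"):
        # the extraction must see the same sampling rate as the cell data
        dt = cell.traces["Pr2"][0].dt
    try:
        traces = {
            name: simulate_step(params, protocols[name], cell.conditions, dt)
            for name in STEP_PROTOCOLS
        }
        sim = assemble_summary(traces, protocols, cell.conditions.E_K)
    except (SimulationError, SummaryError, ModelEvaluationError) as exc:
        logger.debug("e_m2 failure: %s", exc)
        return np.inf

    total = 0.0
    for name, weight in (
        ("act_ss", 1.0),
        ("tau_act", 1.0 / np.max(summary.tau_act.values)),
        ("tau_inact", 1.0 / np.max(summary.tau_inact.values)),
        ("iv", 1.0 / np.ptp(summary.iv.values)),
    ):
        cell_curve = getattr(summary, name)
        values = _aligned(getattr(sim, name), cell_curve)
        if values is None:
            logger.debug("e_m2: simulated %s curve incomplete", name)
            return np.inf
        total += weight * rmse(cell_curve.values, values)
    return total


def _whole_trace_error(
    params: ModelParameters,
    cell: CellDataset,
    protocol: Protocol,
    name: str,
    ode: bool,
    dt: Optional[float],
    rtol: float,
    atol: float,
) -> float:
    if not cell.has(name):
        raise ValueError(f"cell has no {name} traces")
    cell_traces = cell.traces[name]
    dt = cell_traces[0].dt if dt is None else dt
    try:
        if ode:
            sim = simulate_ode(params, protocol, cell.conditions, dt, rtol, atol)
        else:
            sim = simulate_step(params, protocol, cell.conditions, dt)
    except (SimulationError, ModelEvaluationError) as exc:
        logger.debug("whole-trace failure on %s: %s", name, exc)
        return np.inf
    obs = np.concatenate([t.kept_currents() for t in cell_traces])
    pred = np.concatenate([t.kept_currents() for t in sim])
    return rmse(obs, pred) / np.ptp(obs)


def e_m3(
    params: ModelParameters,
    cell: CellDataset,
    protocols: Dict[str, Protocol],
    dt: Optional[float] = None,
) -> float:
    """Whole-trace error over the four step protocols.

    Sum of per-protocol RMSEs, each normalized by the cell's (mask-kept)
    current range for that protocol.
    """
    total = 0.0
    for name in STEP_PROTOCOLS:
        total += _whole_trace_error(
            params, cell, protocols[name], name, ode=False, dt=dt,
            rtol=0.0, atol=0.0,
        )
        if not np.isfinite(total):
            return np.inf
    return total


def e_m4(
    params: ModelParameters,
    cell: CellDataset,
    protocol_pr7: Protocol,
    dt: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> float:
    """Normalized whole-trace error on the sinusoidal protocol only."""
    return _whole_trace_error(
        params, cell, protocol_pr7, "Pr7", ode=True, dt=dt, rtol=rtol, atol=atol
    )


def e_ap(
    params: ModelParameters,
    cell: CellDataset,
    protocol_pr6: Protocol,
    dt: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> float:
    """Validation error on the action-potential waveform protocol, which is
    never used for fitting."""
    return _whole_trace_error(
        params, cell, protocol_pr6, "Pr6", ode=True, dt=dt, rtol=rtol, atol=atol
    )


# ---------------------------------------------------------------------------
# Fast objective factories
#
# The plain e_m2/e_m3/e_m4 functions rebuild protocol encodings and trace
# objects on every call.  Optimizers evaluate the same objective thousands
# of times, so these factories precompute everything that does not depend
# on the parameters and call the compiled kernels directly.


def make_e_m3_objective(
    cell: CellDataset,
    protocols: Dict[str, Protocol],
    dt: Optional[float] = None,
):
    """Closure evaluating the step-protocol whole-trace error."""
    from .protocols import capacitance_mask

    prepared = []
    for name in STEP_PROTOCOLS:
        protocol = protocols[name]
        cell_traces = cell.traces[name]
        use_dt = cell_traces[0].dt if dt is None else dt
        seg_v, seg_dur, seg_lo, seg_hi, n_out, out_lo = [], [], [], [], [], []
        offset_seg = offset_out = 0
        for sweep in protocol.sweeps:
            seg_lo.append(offset_seg)
            for seg in sweep:
                seg_v.append(seg.voltage)
                seg_dur.append(seg.duration)
                offset_seg += 1
            seg_hi.append(offset_seg)
            n = int(np.ceil(sum(s.duration for s in sweep) / use_dt - 1e-9))
            n_out.append(n)
            out_lo.append(offset_out)
            offset_out += n
        keep = np.concatenate(capacitance_mask(protocol, use_dt))
        kept_idx = np.flatnonzero(keep)
        obs = np.concatenate([t.kept_currents() for t in cell_traces])
        if obs.size != kept_idx.size:
            raise ValueError(
                f"{name}: cell traces were not sampled at dt={use_dt}"
            )
        prepared.append(
            (
                np.asarray(seg_v), np.asarray(seg_dur),
                np.asarray(seg_lo), np.asarray(seg_hi),
                np.asarray(n_out), np.asarray(out_lo),
                use_dt, kept_idx, obs, float(np.ptp(obs)),
            )
        )
    e_k = cell.conditions.E_K

    def objective(params: ModelParameters) -> float:
        kin = params.kinetics()
        total = 0.0
        for (seg_v, seg_dur, seg_lo, seg_hi, n_out, out_lo,
             use_dt, kept_idx, obs, rng) in prepared:
            cur, _a, _r = _core.simulate_steps(
                kin, params.p9, e_k, use_dt,
                seg_v, seg_dur, seg_lo, seg_hi, n_out, out_lo,
            )
            pred = cur[kept_idx]
            if not np.all(np.isfinite(pred)):
                return np.inf
            d = obs - pred
            total += np.sqrt(np.mean(d * d)) / rng
        return float(total)

    return objective


#: Stiffness guard for objective evaluations: when the fastest gate time
#: constant anywhere in the physiological voltage range implies more than
#: this many integrator steps for the protocol, the evaluation is treated
#: as a simulation failure (infinite error) instead of grinding an explicit
#: solver through micro-second relaxations the data cannot resolve anyway.
MAX_EXPECTED_STEPS = 2e5

_GUARD_VOLTAGES = (-120.0, 60.0)


def _min_tau(params: ModelParameters) -> float:
    """Smallest gate time constant over the guarded voltage extremes (each
    rate sum is a sum of exponentials in V, so extremes are at endpoints)."""
    worst = np.inf
    for v in _GUARD_VOLTAGES:
        k1 = params.p1 * np.exp(params.p2 * v)
        k2 = params.p3 * np.exp(-params.p4 * v)
        k3 = params.p5 * np.exp(params.p6 * v)
        k4 = params.p7 * np.exp(-params.p8 * v)
        worst = min(worst, 1.0 / (k1 + k2), 1.0 / (k3 + k4))
    return worst


def _make_ode_trace_objective(
    cell: CellDataset,
    protocol: Protocol,
    name: str,
    dt: Optional[float],
    rtol: float,
    atol: float,
    engine: str = "rl",
    substeps: int = 2,
):
    from .model import steady_state
    from .protocols import capacitance_mask
    from .simulate import _encode_sweep

    cell_traces = cell.traces[name]
    use_dt = cell_traces[0].dt if dt is None else dt
    sweeps = []
    for i, sweep in enumerate(protocol.sweeps):
        encoded = _encode_sweep(sweep)
        t_eval = protocol.sample_times(i, use_dt)
        voltages = protocol.sample_voltages(i, use_dt)
        # midpoint voltages of the (t[i-1], t[i]] intervals for the
        # exponential-update tables; entry 0 is unused by the recurrence
        t_mid = t_eval - 0.5 * use_dt
        t_mid[0] = 0.0
        v_mid = protocol.voltages_at(i, t_mid)
        mask = capacitance_mask(protocol, use_dt)[i]
        kept_idx = np.flatnonzero(mask)
        v0 = sweep[0].start_voltage()
        sweeps.append((encoded, t_eval, voltages, v_mid, kept_idx, v0))
    obs = np.concatenate([t.kept_currents() for t in cell_traces])
    rng = float(np.ptp(obs))
    e_k = cell.conditions.E_K

    total_duration = protocol.total_duration()

    def objective(params: ModelParameters) -> float:
        if engine == "adaptive" and total_duration / _min_tau(params) > MAX_EXPECTED_STEPS:
            return np.inf
        kin = params.kinetics()
        preds = []
        for encoded, t_eval, voltages, v_mid, kept_idx, v0 in sweeps:
            s0 = steady_state(params, v0)
            if engine == "rl":
                with np.errstate(over="ignore", invalid="ignore"):
                    k1 = params.p1 * np.exp(params.p2 * v_mid)
                    k2 = params.p3 * np.exp(-params.p4 * v_mid)
                    k3 = params.p5 * np.exp(params.p6 * v_mid)
                    k4 = params.p7 * np.exp(-params.p8 * v_mid)
                    inv_ta = k1 + k2
                    inv_tr = k3 + k4
                    a = _core.gate_recurrence(
                        s0.a, k1 / inv_ta, np.exp(-use_dt * inv_ta)
                    )
                    r = _core.gate_recurrence(
                        s0.r, k4 / inv_tr, np.exp(-use_dt * inv_tr)
                    )
            else:
                a, r, status = _core.integrate_sweep(
                    kin, s0.a, s0.r, *encoded, t_eval, rtol, atol
                )
                if status != 0:
                    return np.inf
            cur = params.p9 * a * r * (voltages - e_k)
            preds.append(cur[kept_idx])
        pred = np.concatenate(preds) if len(preds) > 1 else preds[0]
        if not np.all(np.isfinite(pred)):
            return np.inf
        d = obs - pred
        return float(np.sqrt(np.mean(d * d)) / rng)

    return objective


def make_e_m4_objective(
    cell: CellDataset,
    protocol_pr7: Protocol,
    dt: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    engine: str = "rl",
    substeps: int = 2,
):
    """Closure evaluating the sinusoidal-protocol whole-trace error.

    ``engine="rl"`` (default) uses exponential Rush-Larsen stepping on the
    sample grid — unconditionally stable and fast, accurate to ~1e-4 of the
    current range; ``engine="adaptive"`` uses the reference integrator."""
    return _make_ode_trace_objective(
        cell, protocol_pr7, "Pr7", dt, rtol, atol, engine, substeps
    )


def make_e_ap_objective(
    cell: CellDataset,
    protocol_pr6: Protocol,
    dt: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    engine: str = "rl",
    substeps: int = 2,
):
    """Closure evaluating the validation error on the AP waveform."""
    return _make_ode_trace_objective(
        cell, protocol_pr6, "Pr6", dt, rtol, atol, engine, substeps
    )


def make_e_m2_objective(
    cell: CellDataset,
    protocols: Dict[str, Protocol],
    dt: Optional[float] = None,
):
    """Closure evaluating the simulated-summary-curve error."""

    def objective(params: ModelParameters) -> float:
        return e_m2(params, cell, protocols, dt)

    return objective


def e_all(per_cell_errors) -> float:
    """Multicell aggregate: plain mean (per-cell normalization is already
    built into each measure)."""
    values = np.asarray(list(per_cell_errors), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one per-cell error")
    return float(np.mean(values))
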