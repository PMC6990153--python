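"""Current-trace simulation and trace I/O.

Step protocols are simulated exactly, segment by segment, using the model's
analytic single-exponential solution at fixed voltage.  Protocols with
continuous voltage commands (sampled waveforms, sine sections) are handled
by an adaptive Dormand-Prince integrator with segment boundaries as forced
restart points; the default tolerances of 1e-8 are deliberately strict so
that objective functions built on these simulations are smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from . import _core
from .model import IonicConditions, ModelParameters
from .protocols import Protocol, Sinusoid, Step, Waveform, capacitance_mask

__all__ = [
    "Trace",
    "SimulationError",
    "WrongSimulatorError",
    "TraceFormatError",
    "simulate_step",
    "simulate_ode",
    "simulate",
    "write_trace",
    "read_trace",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-8


class SimulationError(RuntimeError):
    """Integrator failure; carries the offending parameter set."""

    def __init__(self, message: str, params: Optional[ModelParameters] = None):
        super().__init__(message)
        self.params = params


class WrongSimulatorError(TypeError):
    """Protocol contains segments the requested simulator cannot handle."""


class TraceFormatError(ValueError):
    """Malformed trace file."""


@dataclass
class Trace:
    """Uniformly sampled (time, voltage, current) series with a keep-mask."""

    protocol: str
    sweep: int
    times: np.ndarray
    voltages: np.ndarray
    currents: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.times.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.times.size
        if not (self.voltages.size == self.currents.size == self.mask.size == n):
            raise ValueError("trace arrays must have equal length")
        if n > 1:
            steps = np.diff(self.times)
            if np.max(np.abs(steps - steps[0])) > 1e-9:
                raise ValueError("trace times must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def kept_currents(self) -> np.ndarray:
        return self.currents[self.mask]

    def with_currents(self, currents) -> "Trace":
        return Trace(
            self.protocol, self.sweep, self.times, self.voltages,
            np.asarray(currents, dtype=float), self.mask,
        )


# ---------------------------------------------------------------------------
# Simulation


def simulate_step(
    params: ModelParameters,
    protocol: Protocol,
    conditions: IonicConditions,
    dt: Optional[float] = None,
) -> List[Trace]:
    """Exact analytic simulation of a constant-step protocol.

    Gates start at the steady state of the first segment's voltage and carry
    across segments; samples lie on the uniform dt grid.
    """
    if not protocol.is_step_protocol():
        raise WrongSimulatorError(
            f"{protocol.name} contains non-step segments; use simulate_ode"
        )
    dt = protocol.dt if dt is None else dt

    seg_v, seg_dur, seg_lo, seg_hi, n_out, out_lo = [], [], [], [], [], []
    offset_seg = 0
    offset_out = 0
    for sweep in protocol.sweeps:
        seg_lo.append(offset_seg)
        for seg in sweep:
            seg_v.append(seg.voltage)
            seg_dur.append(seg.duration)
            offset_seg += 1
        seg_hi.append(offset_seg)
        dur = sum(seg.duration for seg in sweep)
        n = int(np.ceil(dur / dt - 1e-9))
        n_out.append(n)
        out_lo.append(offset_out)
        offset_out += n

    cur, _a, _r = _core.simulate_steps(
        params.kinetics(), params.p9, conditions.E_K, dt,
        np.asarray(seg_v), np.asarray(seg_dur),
        np.asarray(seg_lo), np.asarray(seg_hi),
        np.asarray(n_out), np.asarray(out_lo),
    )
    if not np.all(np.isfinite(cur)):
        raise SimulationError("non-finite current in analytic simulation", params)

    masks = capacitance_mask(protocol, dt)
    traces = []
    for i in range(protocol.n_sweeps):
        times = protocol.sample_times(i, dt)
        voltages = protocol.sample_voltages(i, dt)
        sl = slice(out_lo[i], out_lo[i] + n_out[i])
        traces.append(
            Trace(protocol.name, i, times, voltages, cur[sl], masks[i])
        )
    return traces


def _encode_sweep(sweep):
    """Flatten a sweep's segments into the arrays the integrator expects."""
    n = len(sweep)
    kind = np.zeros(n, dtype=np.int64)
    seg_v = np.zeros(n)
    seg_dur = np.zeros(n)
    sine_amp = np.zeros((n, 3))
    sine_om = np.zeros((n, 3))
    sine_ph = np.zeros((n, 3))
    wf_t_parts, wf_v_parts = [], []
    wf_lo = np.zeros(n, dtype=np.int64)
    wf_hi = np.zeros(n, dtype=np.int64)
    pos = 0
    for j, seg in enumerate(sweep):
        seg_dur[j] = seg.duration
        if isinstance(seg, Step):
            kind[j] = _core.KIND_STEP
            seg_v[j] = seg.voltage
        elif isinstance(seg, Sinusoid):
            kind[j] = _core.KIND_SINE
            seg_v[j] = seg.offset
            sine_amp[j] = seg.amplitudes
            sine_om[j] = seg.omegas
            sine_ph[j] = seg.phases
        elif isinstance(seg, Waveform):
            kind[j] = _core.KIND_WAVEFORM
            wf_lo[j] = pos
            wf_t_parts.append(seg.times)
            wf_v_parts.append(seg.voltages)
            pos += seg.times.size
            wf_hi[j] = pos
        else:  # pragma: no cover
            raise WrongSimulatorError(f"unknown segment type {type(seg)!r}")
    wf_t = np.concatenate(wf_t_parts) if wf_t_parts else np.zeros(0)
    wf_v = np.concatenate(wf_v_parts) if wf_v_parts else np.zeros(0)
    return kind, seg_v, seg_dur, sine_amp, sine_om, sine_ph, wf_t, wf_v, wf_lo, wf_hi


def simulate_ode(
    params: ModelParameters,
    protocol: Protocol,
    conditions: IonicConditions,
    dt: Optional[float] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> List[Trace]:
    """Adaptive-step integration of the gating ODEs for any protocol."""
    from .model import steady_state

    dt = protocol.dt if dt is None else dt
    masks = capacitance_mask(protocol, dt)
    traces = []
    for i, sweep in enumerate(protocol.sweeps):
        encoded = _encode_sweep(sweep)
        first = sweep[0]
        v0 = first.start_voltage()
        state0 = steady_state(params, v0)
        times = protocol.sample_times(i, dt)
        a, r, status = _core.integrate_sweep(
            params.kinetics(), state0.a, state0.r, *encoded, times, rtol, atol
        )
        if status != 0 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(r))):
            raise SimulationError(
                f"integration failed on {protocol.name} sweep {i}", params
            )
        voltages = protocol.sample_voltages(i, dt)
        currents = params.p9 * a * r * (voltages - conditions.E_K)
        traces.append(Trace(protocol.name, i, times, voltages, currents, masks[i]))
    return traces


def simulate(
    params: ModelParameters,
    protocol: Protocol,
    conditions: IonicConditions,
    dt: Optional[float] = None,
    solver: str = "auto",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> List[Trace]:
    """Dispatch to the analytic solver for step protocols, ODE otherwise."""
    if solver == "analytic" or (solver == "auto" and protocol.is_step_protocol()):
        return simulate_step(params, protocol, conditions, dt)
    if solver in ("ode", "auto"):
        return simulate_ode(params, protocol, conditions, dt, rtol, atol)
    raise ValueError(f"unknown solver {solver!r}")


# ---------------------------------------------------------------------------
# Trace I/O


def write_trace(trace: Trace, path: Union[str, Path]) -> None:
    """Write a trace as CSV with columns time_ms, voltage_mV, current, keep."""
    df = pd.DataFrame(
        {
            "time_ms": trace.times,
            "voltage_mV": trace.voltages,
            "current": trace.currents,
            "keep": trace.mask.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# protocol: {trace.protocol}\n# sweep: {trace.sweep}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trace(path: Union[str, Path]) -> Trace:
    """Read a trace CSV; the ``keep`` column and metadata lines are optional."""
    path = Path(path)
    name, sweep = "unknown", 0
    with open(path) as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                key = key.strip().lower()
                if key == "protocol":
                    name = value.strip()
                elif key == "sweep":
                    sweep = int(value)
            else:
                head.append(line)
                break
        if not head:
            raise TraceFormatError(f"no data in {path}")
        df = pd.read_csv(fh, header=None, names=head[0].strip().split(","),
                         float_precision="round_trip")
    for col in ("time_ms", "voltage_mV", "current"):
        if col not in df.columns:
            raise TraceFormatError(f"missing column {col!r} in {path}")
    if df.shape[0] == 0:
        raise TraceFormatError(f"no samples in {path}")
    mask = (
        df["keep"].to_numpy().astype(bool) if "keep" in df.columns else None
    )
    return Trace(
        name,
        sweep,
        df["time_ms"].to_numpy(float),
        df["voltage_mV"].to_numpy(float),
        df["current"].to_numpy(float),
        mask,
    )
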