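"""Voltage-clamp protocol definitions (Pr2-Pr7) and the capacitance mask.

A :class:`Protocol` is an ordered list of sweeps; each sweep is an ordered
list of segments.  Segments are either constant-voltage steps, sampled
waveforms (used for the action-potential protocol Pr6) or sums of sine
waves on a constant offset (the short system-identification protocol Pr7).

The default step protocols are read from ``data/protocols.yaml`` so that
their voltage/duration grids can be corrected without code changes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import yaml

__all__ = [
    "Step",
    "Waveform",
    "Sinusoid",
    "Protocol",
    "ProtocolConfigError",
    "default_config",
    "build_pr2",
    "build_pr3",
    "build_pr4",
    "build_pr5",
    "build_pr7",
    "build_default_protocols",
    "load_sampled_protocol",
    "write_sampled_protocol",
    "capacitance_mask",
]

#: Default blanking window after a voltage discontinuity (ms).
CAPACITANCE_WINDOW = 5.0

#: Two constant levels differing by less than this (mV) are continuous.
DISCONTINUITY_TOL = 1e-9


class ProtocolConfigError(ValueError):
    """Raised for malformed protocol configurations or waveform files."""


@dataclass(frozen=True)
class Step:
    """Constant-voltage segment."""

    duration: float
    voltage: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ProtocolConfigError("segment duration must be positive")

    def voltage_at(self, t: float) -> float:
        return self.voltage

    def start_voltage(self) -> float:
        return self.voltage

    def end_voltage(self) -> float:
        return self.voltage


@dataclass(frozen=True)
class Waveform:
    """Sampled voltage waveform; linear interpolation between nodes.

    ``times`` are segment-local, strictly increasing, starting at 0 and
    ending at ``duration``.
    """

    duration: float
    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ProtocolConfigError("waveform needs >= 2 (time, voltage) nodes")
        if np.any(np.diff(t) <= 0):
            raise ProtocolConfigError("waveform times must be strictly increasing")
        if abs(t[0]) > 1e-12 or abs(t[-1] - self.duration) > 1e-9:
            raise ProtocolConfigError("waveform times must span exactly the duration")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)
        if self.duration <= 0:
            raise ProtocolConfigError("segment duration must be positive")

    def voltage_at(self, t):
        return np.interp(t, self.times, self.voltages)

    def start_voltage(self) -> float:
        return float(self.voltages[0])

    def end_voltage(self) -> float:
        return float(self.voltages[-1])


@dataclass(frozen=True)
class Sinusoid:
    """Constant offset plus three summed sine components.

    ``V(t) = offset + sum_j amplitudes[j] * sin(omegas[j] * t + phases[j])``
    with t measured from the segment start (ms, omegas in rad/ms).
    """

    duration: float
    offset: float
    amplitudes: tuple
    omegas: tuple
    phases: tuple

    def __post_init__(self):
        if self.duration <= 0:
            raise ProtocolConfigError("segment duration must be positive")
        for name in ("amplitudes", "omegas", "phases"):
            vals = tuple(float(x) for x in getattr(self, name))
            if len(vals) != 3:
                raise ProtocolConfigError(f"{name} must have exactly 3 entries")
            object.__setattr__(self, name, vals)

    def voltage_at(self, t):
        t = np.asarray(t, dtype=float)
        v = np.full(t.shape, self.offset)
        for amp, om, ph in zip(self.amplitudes, self.omegas, self.phases):
            v = v + amp * np.sin(om * t + ph)
        return v if v.ndim else float(v)

    def start_voltage(self) -> float:
        return float(self.voltage_at(0.0))

    def end_voltage(self) -> float:
        return float(self.voltage_at(self.duration))


Segment = Union[Step, Waveform, Sinusoid]


@dataclass
class Protocol:
    """An ordered list of sweeps, each an ordered list of segments."""

    name: str
    sweeps: List[List[Segment]]
    dt: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.sweeps or any(not s for s in self.sweeps):
            raise ProtocolConfigError("protocol needs at least one non-empty sweep")
        if self.dt <= 0:
            raise ProtocolConfigError("dt must be positive")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweep_duration(self, sweep: int) -> float:
        return float(sum(seg.duration for seg in self.sweeps[sweep]))

    def total_duration(self) -> float:
        return float(sum(self.sweep_duration(i) for i in range(self.n_sweeps)))

    def segment_starts(self, sweep: int) -> np.ndarray:
        durs = [seg.duration for seg in self.sweeps[sweep]]
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    def is_step_protocol(self) -> bool:
        return all(
            isinstance(seg, Step) for sweep in self.sweeps for seg in sweep
        )

    def voltage_at(self, sweep: int, t: float) -> float:
        """Commanded voltage at sweep-local time t (ms)."""
        total = self.sweep_duration(sweep)
        if t < 0 or t >= total:
            raise ValueError(f"t={t} outside sweep of duration {total} ms")
        start = 0.0
        for seg in self.sweeps[sweep]:
            if t < start + seg.duration:
                return float(seg.voltage_at(t - start))
            start += seg.duration
        raise AssertionError("unreachable")  # pragma: no cover

    def sample_times(self, sweep: int, dt: Optional[float] = None) -> np.ndarray:
        """Uniform sample grid covering [0, duration) of a sweep."""
        dt = self.dt if dt is None else dt
        n = int(np.ceil(self.sweep_duration(sweep) / dt - 1e-9))
        return np.arange(n) * dt

    def voltages_at(self, sweep: int, times) -> np.ndarray:
        """Commanded voltage at arbitrary sweep-local times (vectorized).
        Times at or beyond the sweep end take the final segment's level."""
        t = np.asarray(times, dtype=float)
        v = np.empty_like(t)
        start = 0.0
        for seg in self.sweeps[sweep]:
            sel = (t >= start - 1e-9) & (t < start + seg.duration - 1e-9)
            v[sel] = seg.voltage_at(t[sel] - start)
            start += seg.duration
        v[t >= start - 1e-9] = self.sweeps[sweep][-1].end_voltage()
        return v

    def sample_voltages(self, sweep: int, dt: Optional[float] = None) -> np.ndarray:
        """Commanded voltage on the sample grid."""
        dt = self.dt if dt is None else dt
        return self.voltages_at(sweep, self.sample_times(sweep, dt))


# ---------------------------------------------------------------------------
# Default configuration


def default_config() -> dict:
    """Load the packaged default protocol configuration."""
    from importlib import resources

    with resources.files("ikrfit.data").joinpath("protocols.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merged(config: Optional[dict], key: str) -> dict:
    base = default_config()
    cfg = copy.deepcopy(base[key])
    cfg["dt"] = base["dt"]
    if config:
        if key in config:
            cfg.update(copy.deepcopy(config[key]))
        if "dt" in config:
            cfg["dt"] = config["dt"]
    return cfg


def _step(entry: dict) -> Step:
    return Step(duration=float(entry["duration"]), voltage=float(entry["voltage"]))


def build_pr2(config: Optional[dict] = None) -> Protocol:
    """Activation-time-constant protocol: repeated sweeps with increasing
    duration of a fixed-voltage P1 step (default +40 mV), followed by a
    fixed tail step."""
    cfg = _merged(config, "pr2")
    durations = [float(d) for d in cfg["p1_durations"]]
    if any(b <= a for a, b in zip(durations, durations[1:])):
        raise ProtocolConfigError("P1 durations must be strictly increasing")
    sweeps = [
        [
            _step(cfg["holding"]),
            Step(duration=d, voltage=float(cfg["p1_voltage"])),
            _step(cfg["tail"]),
            _step(cfg["final"]),
        ]
        for d in durations
    ]
    meta = {
        "roles": ["holding", "p1", "tail", "final"],
        "p1_voltage": float(cfg["p1_voltage"]),
        "p1_durations": durations,
        "varying": "p1",
    }
    return Protocol("Pr2", sweeps, dt=float(cfg["dt"]), meta=meta)


def build_pr3(config: Optional[dict] = None) -> Protocol:
    """Steady-state-of-activation protocol: sweeps varying the P1 voltage,
    with a fixed long P1 duration and a fixed tail step."""
    cfg = _merged(config, "pr3")
    voltages = [float(v) for v in cfg["p1_voltages"]]
    if len(set(voltages)) != len(voltages):
        raise ProtocolConfigError("P1 voltages must be distinct")
    sweeps = [
        [
            _step(cfg["holding"]),
            Step(duration=float(cfg["p1_duration"]), voltage=v),
            _step(cfg["tail"]),
            _step(cfg["final"]),
        ]
        for v in voltages
    ]
    meta = {
        "roles": ["holding", "p1", "tail", "final"],
        "p1_voltages": voltages,
        "varying": "p1",
    }
    return Protocol("Pr3", sweeps, dt=float(cfg["dt"]), meta=meta)


def build_pr4(config: Optional[dict] = None) -> Protocol:
    """Inactivation-time-constant protocol: fixed P1/P2 conditioning, then a
    P3 step whose voltage varies per sweep."""
    cfg = _merged(config, "pr4")
    voltages = [float(v) for v in cfg["p3_voltages"]]
    if len(set(voltages)) != len(voltages):
        raise ProtocolConfigError("P3 voltages must be distinct")
    sweeps = [
        [
            _step(cfg["holding"]),
            _step(cfg["p1"]),
            _step(cfg["p2"]),
            Step(duration=float(cfg["p3_duration"]), voltage=v),
            _step(cfg["final"]),
        ]
        for v in voltages
    ]
    meta = {
        "roles": ["holding", "p1", "p2", "p3", "final"],
        "p3_voltages": voltages,
        "varying": "p3",
    }
    return Protocol("Pr4", sweeps, dt=float(cfg["dt"]), meta=meta)


def build_pr5(config: Optional[dict] = None) -> Protocol:
    """Combined protocol: fixed activating P1, then a long P2 step whose
    voltage varies per sweep.  Yields the IV curve, the steady state of
    inactivation and time constants of both gates."""
    cfg = _merged(config, "pr5")
    voltages = [float(v) for v in cfg["p2_voltages"]]
    if len(set(voltages)) != len(voltages):
        raise ProtocolConfigError("P2 voltages must be distinct")
    sweeps = [
        [
            _step(cfg["holding"]),
            _step(cfg["p1"]),
            Step(duration=float(cfg["p2_duration"]), voltage=v),
            _step(cfg["final"]),
        ]
        for v in voltages
    ]
    meta = {
        "roles": ["holding", "p1", "p2", "final"],
        "p2_voltages": voltages,
        "varying": "p2",
    }
    return Protocol("Pr5", sweeps, dt=float(cfg["dt"]), meta=meta)


def build_pr7(config: Optional[dict] = None) -> Protocol:
    """Short fluctuating protocol: holding, a +40 mV step that triggers a
    large current, a sum-of-three-sines section, and a return to holding."""
    cfg = _merged(config, "pr7")
    sines = cfg["sines"]
    comps = sines["components"]
    sinusoid = Sinusoid(
        duration=float(sines["duration"]),
        offset=float(sines["offset"]),
        amplitudes=tuple(float(c["amplitude"]) for c in comps),
        omegas=tuple(float(c["omega"]) for c in comps),
        phases=tuple(float(c.get("phase", 0.0)) for c in comps),
    )
    sweep = [_step(cfg["holding"]), _step(cfg["step"]), sinusoid, _step(cfg["final"])]
    meta = {"roles": ["holding", "step", "sines", "final"]}
    return Protocol("Pr7", [sweep], dt=float(cfg["dt"]), meta=meta)


def build_default_protocols(config: Optional[dict] = None) -> dict:
    """All default step protocols plus Pr7, keyed by name."""
    return {
        "Pr2": build_pr2(config),
        "Pr3": build_pr3(config),
        "Pr4": build_pr4(config),
        "Pr5": build_pr5(config),
        "Pr7": build_pr7(config),
    }


# ---------------------------------------------------------------------------
# Sampled (waveform) protocols


def load_sampled_protocol(
    path: Union[str, Path], name: str = "Pr6", dt: float = 0.1
) -> Protocol:
    """Load a two-column (time ms, voltage mV) text file as a single-sweep
    waveform protocol.  Accepts whitespace- or comma-delimited data."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ProtocolConfigError(f"empty waveform file: {path}")
    delimiter = "," if "," in text.splitlines()[0] else None
    data = np.loadtxt(path, delimiter=delimiter, comments="#", ndmin=2)
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 2:
        raise ProtocolConfigError(f"expected two columns of nodes in {path}")
    t, v = data[:, 0], data[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ProtocolConfigError(f"times must be strictly increasing in {path}")
    t = t - t[0]
    segment = Waveform(duration=float(t[-1]), times=t, voltages=v)
    return Protocol(name, [[segment]], dt=dt, meta={"roles": ["waveform"]})


def write_sampled_protocol(protocol: Protocol, path: Union[str, Path]) -> None:
    """Write a single-sweep waveform protocol back to two-column text."""
    (segment,) = protocol.sweeps[0]
    if not isinstance(segment, Waveform):
        raise ProtocolConfigError("only waveform protocols can be exported this way")
    np.savetxt(
        path,
        np.column_stack([segment.times, segment.voltages]),
        fmt="%.12g",
        header="time_ms voltage_mV",
    )


# ---------------------------------------------------------------------------
# Capacitance-artifact mask


def discontinuity_times(protocol: Protocol, sweep: int) -> np.ndarray:
    """Sweep-local times of discontinuous voltage steps.

    A discontinuity exists at any internal segment boundary where the left
    and right voltage limits differ by more than 1e-9 mV.  Sweep starts are
    not treated as discontinuities: sweeps begin at the holding level the
    cell is already clamped to.
    """
    times = []
    start = 0.0
    segs = protocol.sweeps[sweep]
    for left, right in zip(segs[:-1], segs[1:]):
        start += left.duration
        if abs(left.end_voltage() - right.start_voltage()) > DISCONTINUITY_TOL:
            times.append(start)
    return np.asarray(times)


def capacitance_mask(
    protocol: Protocol,
    dt: Optional[float] = None,
    window: float = CAPACITANCE_WINDOW,
) -> List[np.ndarray]:
    """Per-sweep boolean keep-masks blanking ``window`` ms after each
    discontinuous voltage step.

    The mask depends only on the voltage command, so the identical mask is
    applied to measured and simulated data.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    dt = protocol.dt if dt is None else dt
    masks = []
    for sweep in range(protocol.n_sweeps):
        t = protocol.sample_times(sweep, dt)
        keep = np.ones(t.shape, dtype=bool)
        for td in discontinuity_times(protocol, sweep):
            keep &= ~((t >= td - 1e-9) & (t < td + window - 1e-9))
        masks.append(keep)
    return masks
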