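"""Extraction of the five summary curves from current traces.

This analysis is applied *identically* to measured and simulated data: the
steady state of activation from Pr3 tail peaks, the steady state of
inactivation and IV curve from the Pr5 P2 step, the activation time
constant from the Pr2 envelope and Pr5 slow phase, and the inactivation
time constant from the Pr4 onset and Pr5 fast phase.

Exponential fits search over log time constants (coarse grid scan plus
golden-section or Nelder-Mead refinement) with the linear parameters
(amplitudes, offset) profiled out by least squares at every step; this
keeps the time constants strictly positive and the fit cheap enough to sit
inside an objective function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .protocols import Protocol
from .simulate import Trace

__all__ = [
    "ExpFit",
    "Curve",
    "SummarySet",
    "SummaryError",
    "fit_exponential",
    "tau_act_from_pr2",
    "act_ss_from_pr3",
    "tau_inact_from_pr4",
    "analyse_pr5",
    "assemble_summary",
]

logger = logging.getLogger(__name__)

#: Signals whose range is below this floor are reported as unfittable.
FLAT_FLOOR = 1e-12

#: Exponential fits are evaluated on at most this many (evenly thinned)
#: samples; noiseless recovery is unaffected and objective evaluations that
#: embed the extraction pipeline stay fast.
MAX_FIT_POINTS = 150

#: Default onset window (ms) for the fast (inactivation) phase of Pr5 P2,
#: and start of the slow (deactivation) phase window.
FAST_WINDOW = 50.0

#: Pr4 onset-fit window (ms).
PR4_FIT_WINDOW = 150.0

#: Voltage-range selection rules for the time-constant curves (mV).
PR4_TAU_R_VMIN = -40.0
PR5_TAU_R_VMAX = -30.0
PR5_TAU_A_VMAX = 0.0


class SummaryError(RuntimeError):
    """Summary-curve derivation failed (flat signals, missing data...)."""


@dataclass(frozen=True)
class ExpFit:
    """One exponential component ``offset + amplitude * exp(-t / tau)``."""

    amplitude: float
    tau: float
    offset: float
    rss: float


@dataclass(frozen=True)
class Curve:
    """A summary curve: values on a voltage grid, sorted by voltage."""

    voltages: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.voltages, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if v.shape != y.shape or v.ndim != 1:
            raise ValueError("curve voltages/values must be equal-length 1-D")
        order = np.argsort(v)
        object.__setattr__(self, "voltages", v[order])
        object.__setattr__(self, "values", y[order])

    def __len__(self) -> int:
        return self.voltages.size


@dataclass(frozen=True)
class SummarySet:
    """The five experimental summary curves of one cell."""

    act_ss: Curve      # steady state of activation (Pr3)
    inact_ss: Curve    # steady state of inactivation (Pr5)
    tau_act: Curve     # activation time constant (Pr5 + Pr2), ms
    tau_inact: Curve   # inactivation time constant (Pr5 + Pr4), ms
    iv: Curve          # peak current during the Pr5 P2 step

    def counts(self) -> Tuple[int, int, int, int, int]:
        return (
            len(self.act_ss),
            len(self.inact_ss),
            len(self.tau_act),
            len(self.tau_inact),
            len(self.iv),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("act_ss", "inact_ss", "tau_act", "tau_inact", "iv"):
            curve = getattr(self, name)
            for v, y in zip(curve.voltages, curve.values):
                rows.append({"curve": name, "voltage_mV": v, "value": y})
        return pd.DataFrame(rows)

    def save(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SummarySet":
        df = pd.read_csv(path, float_precision="round_trip")
        curves = {}
        for name, group in df.groupby("curve"):
            curves[name] = Curve(
                group["voltage_mV"].to_numpy(float), group["value"].to_numpy(float)
            )
        return cls(**curves)


# ---------------------------------------------------------------------------
# Exponential fitting


def _thin(times: np.ndarray, values: np.ndarray, max_points: int):
    if times.size <= max_points:
        return times, values
    idx = np.unique(np.linspace(0, times.size - 1, max_points).astype(int))
    return times[idx], values[idx]


def _profiled_sse(t: np.ndarray, v: np.ndarray, taus: np.ndarray):
    """SSE minimized over amplitudes and offset for fixed time constants.

    The normal equations are 2x2 (one phase) or 3x3 (two phases) and are
    solved in closed form — this sits in the innermost loop of the
    simulated-summary objective.
    """
    n = t.size
    sv = float(np.sum(v))
    vv = float(v @ v)
    if taus.size == 1:
        e = np.exp(-t / taus[0])
        ee = float(e @ e)
        se = float(np.sum(e))
        ev = float(e @ v)
        det = ee * n - se * se
        if abs(det) < 1e-30:
            return vv - sv * sv / n, np.array([0.0, sv / n])
        amp = (ev * n - se * sv) / det
        off = (ee * sv - se * ev) / det
        sse = vv - amp * ev - off * sv
        return max(float(sse), 0.0), np.array([amp, off])
    cols = [np.exp(-t / tau) for tau in taus] + [np.ones_like(t)]
    A = np.column_stack(cols)
    G = A.T @ A
    try:
        coef = np.linalg.solve(G, A.T @ v)
    except np.linalg.LinAlgError:
        coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - A @ coef
    return float(resid @ resid), coef


def fit_exponential(
    times,
    values,
    n_phases: int = 1,
    flat_floor: float = FLAT_FLOOR,
    max_points: int = MAX_FIT_POINTS,
    tau_range: Optional[Tuple[float, float]] = None,
):
    """Least-squares fit of a sum of decaying exponentials plus an offset.

    The time constant(s) are found by a deterministic coarse scan over
    log-spaced values in ``tau_range`` (default: sample spacing to ten
    times the record length) followed by a Nelder-Mead polish in log space,
    with the amplitudes and offset profiled out by linear least squares at
    every step.  Positivity of tau is therefore structural.

    Returns an :class:`ExpFit` (or a fast-to-slow ordered tuple of two for
    ``n_phases=2``), or ``None`` when the signal is flat below
    ``flat_floor`` or the fit degenerates — the caller then omits the point
    from its summary curve.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if t.size < 2 + 2 * n_phases:
        raise ValueError(f"need at least {2 + 2 * n_phases} samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(v) < flat_floor:
        return None

    t0 = t[0]
    t, v = _thin(t - t0, v, max_points)
    span = t[-1]
    if tau_range is None:
        tau_range = (max(np.min(np.diff(t)) * 0.25, 1e-6), 10.0 * span)
    lo, hi = np.log(tau_range[0]), np.log(tau_range[1])

    def objective(log_taus):
        for x in log_taus:
            if x < lo - 1e-12 or x > hi + 1e-12:
                return np.inf
        sse, _ = _profiled_sse(t, v, np.exp(log_taus))
        return sse

    grid = np.linspace(lo, hi, 18)
    if n_phases == 1:
        # bracket on the grid, then golden-section refinement in log space
        scores = [objective(np.array([g])) for g in grid]
        k = int(np.argmin(scores))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, grid.size - 1)]
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = objective(np.array([c]))
        fd = objective(np.array([d]))
        for _ in range(60):
            if b - a < 1e-10:
                break
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = objective(np.array([c]))
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = objective(np.array([d]))
        best_log_tau = c if fc < fd else d
        taus = np.exp(np.clip(np.array([best_log_tau]), lo, hi))
        sse, coef = _profiled_sse(t, v, taus)
        if not (np.all(np.isfinite(taus)) and np.all(np.isfinite(coef))):
            return None
        return ExpFit(
            amplitude=float(coef[0]), tau=float(taus[0]),
            offset=float(coef[1]), rss=sse,
        )
    else:
        best_pair, best_sse = None, np.inf
        for ii in range(0, grid.size, 2):
            for jj in range(ii + 2, grid.size, 2):
                sse = objective(np.array([grid[ii], grid[jj]]))
                if sse < best_sse:
                    best_sse, best_pair = sse, (grid[ii], grid[jj])
        if best_pair is None:
            return None
        x0 = np.array(best_pair)

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-300, "maxiter": 90 * n_phases},
    )
    taus = np.sort(np.exp(np.clip(res.x, lo, hi)))  # fast first
    sse, coef = _profiled_sse(t, v, taus)
    if not (np.all(np.isfinite(taus)) and np.all(np.isfinite(coef))):
        return None
    offset = float(coef[-1])
    fits = tuple(
        ExpFit(amplitude=float(c), tau=float(tau), offset=offset, rss=sse)
        for c, tau in zip(coef[:-1], taus)
    )
    return fits[0] if n_phases == 1 else fits


# ---------------------------------------------------------------------------
# Per-protocol extraction helpers


def _segment_samples(
    protocol: Protocol, trace: Trace, sweep: int, seg_index: int
) -> Tuple[np.ndarray, np.ndarray]:
    """(local times, currents) of the mask-kept samples in one segment."""
    dt = trace.dt
    starts = protocol.segment_starts(sweep)
    t0 = starts[seg_index]
    dur = protocol.sweeps[sweep][seg_index].duration
    i0 = int(np.ceil(t0 / dt - 1e-9))
    i1 = min(int(np.ceil((t0 + dur) / dt - 1e-9)), trace.times.size)
    keep = trace.mask[i0:i1]
    t_local = trace.times[i0:i1][keep] - t0
    return t_local, trace.currents[i0:i1][keep]


def _signed_peak(currents: np.ndarray) -> float:
    """Signed extremum of largest magnitude (tail currents change sign
    across the reversal potential)."""
    return float(currents[np.argmax(np.abs(currents))])


def _role_index(protocol: Protocol, role: str) -> int:
    return protocol.meta["roles"].index(role)


def tau_act_from_pr2(traces: List[Trace], protocol: Protocol):
    """Single activation time constant at the Pr2 P1 voltage (default +40).

    The peak tail current after each P1 duration traces out a saturating
    envelope; a single exponential in the P1 duration gives the time
    constant.  Returns ``(voltage, tau)`` or ``None``.
    """
    tail = _role_index(protocol, "tail")
    durations = protocol.meta["p1_durations"]
    ds, peaks = [], []
    for i, (trace, duration) in enumerate(zip(traces, durations)):
        _, cur = _segment_samples(protocol, trace, i, tail)
        if cur.size == 0:
            continue
        ds.append(duration)
        peaks.append(_signed_peak(cur))
    if len(peaks) < 4:
        logger.warning("Pr2: fewer than 4 usable tail peaks; no tau estimate")
        return None
    fit = fit_exponential(np.asarray(ds), np.asarray(peaks), 1)
    if fit is None:
        logger.warning("Pr2: envelope fit failed; no tau estimate")
        return None
    return (float(protocol.meta["p1_voltage"]), fit.tau)


def act_ss_from_pr3(traces: List[Trace], protocol: Protocol) -> Curve:
    """Steady state of activation: normalized peak tail currents vs the P1
    voltage.  Values are scaled by the largest absolute peak and clipped to
    [0, 1]."""
    tail = _role_index(protocol, "tail")
    voltages = protocol.meta["p1_voltages"]
    peaks = []
    for i, trace in enumerate(traces):
        _, cur = _segment_samples(protocol, trace, i, tail)
        if cur.size == 0:
            raise SummaryError("Pr3: empty tail segment")
        peaks.append(_signed_peak(cur))
    peaks = np.asarray(peaks)
    largest = np.max(np.abs(peaks))
    if largest <= 0:
        raise SummaryError("Pr3: all tail currents are zero")
    return Curve(np.asarray(voltages), np.clip(peaks / largest, 0.0, 1.0))


def tau_inact_from_pr4(
    traces: List[Trace],
    protocol: Protocol,
    v_min: float = PR4_TAU_R_VMIN,
    fit_window: float = PR4_FIT_WINDOW,
) -> Curve:
    """Inactivation time constants from the current onset during P3, for
    sweeps with P3 voltage at ``v_min`` (default -40 mV) and above."""
    p3 = _role_index(protocol, "p3")
    voltages = protocol.meta["p3_voltages"]
    vs, taus = [], []
    for i, (trace, v) in enumerate(zip(traces, voltages)):
        if v < v_min - 1e-9:
            continue
        t_local, cur = _segment_samples(protocol, trace, i, p3)
        sel = t_local <= fit_window + 1e-9
        fit = (
            fit_exponential(
                t_local[sel], cur[sel], 1, tau_range=(0.05, 4.0 * fit_window)
            )
            if np.count_nonzero(sel) >= 4
            else None
        )
        if fit is None:
            logger.warning("Pr4: onset fit failed at %s mV; point omitted", v)
            continue
        vs.append(v)
        taus.append(fit.tau)
    return Curve(np.asarray(vs), np.asarray(taus))


def analyse_pr5(
    traces: List[Trace],
    protocol: Protocol,
    E_K: float,
    fast_window: float = FAST_WINDOW,
    tau_r_vmax: float = PR5_TAU_R_VMAX,
    tau_a_vmax: float = PR5_TAU_A_VMAX,
) -> Dict[str, Curve]:
    """All Pr5-derived quantities from the long P2 step.

    Per sweep: the IV point is the signed peak current during P2; the fast
    onset phase (first ``fast_window`` ms after masking) gives the
    inactivation time constant for P2 voltages below ``tau_r_vmax``; the
    remaining slow phase gives the activation (deactivation) time constant
    for voltages below ``tau_a_vmax``.  The steady state of inactivation is
    the peak current divided by the driving force, normalized to a maximum
    of one, with the P2 voltage nearest E_K excluded.
    """
    p2 = _role_index(protocol, "p2")
    voltages = np.asarray(protocol.meta["p2_voltages"], dtype=float)

    iv_vals = np.empty(voltages.size)
    tau_r_v, tau_r = [], []
    tau_a_v, tau_a = [], []
    for i, (trace, v) in enumerate(zip(traces, voltages)):
        t_local, cur = _segment_samples(protocol, trace, i, p2)
        if cur.size == 0:
            raise SummaryError("Pr5: empty P2 segment")
        iv_vals[i] = _signed_peak(cur)

        # Slow (deactivation) phase on the window after the fast transient.
        slow_fit = None
        slow_ref = None
        if v < max(tau_a_vmax, tau_r_vmax) - 1e-9:
            sel = t_local >= t_local[0] + fast_window
            if np.count_nonzero(sel) >= 4:
                slow_ref = t_local[sel][0]
                slow_fit = fit_exponential(t_local[sel], cur[sel], 1)

        if v < tau_a_vmax - 1e-9:
            if slow_fit is None:
                logger.warning("Pr5: slow-phase fit failed at %s mV", v)
            else:
                tau_a_v.append(v)
                tau_a.append(slow_fit.tau)

        if v < tau_r_vmax - 1e-9:
            # The onset mixes the fast recovery transient with the start of
            # the slow deactivation: peel off the extrapolated slow phase and
            # fit a single exponential to the residual.
            sel = t_local <= t_local[0] + fast_window
            t_on, c_on = t_local[sel], cur[sel]
            if slow_fit is not None:
                c_on = c_on - (
                    slow_fit.offset
                    + slow_fit.amplitude
                    * np.exp(-(t_on - slow_ref) / slow_fit.tau)
                )
            fit = (
                fit_exponential(t_on, c_on, 1, tau_range=(0.05, 2.0 * fast_window))
                if t_on.size >= 4
                else None
            )
            if fit is None:
                logger.warning("Pr5: fast-phase fit failed at %s mV", v)
            else:
                tau_r_v.append(v)
                tau_r.append(fit.tau)

    drive = voltages - E_K
    nearest = int(np.argmin(np.abs(drive)))
    keep = np.ones(voltages.size, dtype=bool)
    keep[nearest] = False
    rinf_raw = iv_vals[keep] / drive[keep]
    top = np.max(rinf_raw)
    if top <= 0:
        raise SummaryError("Pr5: degenerate steady-state-of-inactivation curve")

    return {
        "iv": Curve(voltages, iv_vals),
        "inact_ss": Curve(voltages[keep], np.clip(rinf_raw / top, 0.0, 1.0)),
        "tau_act": Curve(np.asarray(tau_a_v), np.asarray(tau_a)),
        "tau_inact": Curve(np.asarray(tau_r_v), np.asarray(tau_r)),
    }


def assemble_summary(
    traces: Dict[str, List[Trace]],
    protocols: Dict[str, Protocol],
    E_K: float,
) -> SummarySet:
    """Merge the per-protocol extractions into a full :class:`SummarySet`.

    The activation time constant combines the Pr5 slow-phase points with
    the single Pr2 envelope point; the inactivation time constant combines
    the Pr5 fast-phase points with the Pr4 onset points.
    """
    for name in ("Pr2", "Pr3", "Pr4", "Pr5"):
        if name not in traces or name not in protocols:
            raise SummaryError(f"incomplete dataset: missing {name}")

    act_ss = act_ss_from_pr3(traces["Pr3"], protocols["Pr3"])
    pr5 = analyse_pr5(traces["Pr5"], protocols["Pr5"], E_K)
    pr4 = tau_inact_from_pr4(traces["Pr4"], protocols["Pr4"])
    pr2 = tau_act_from_pr2(traces["Pr2"], protocols["Pr2"])

    tau_act_v = list(pr5["tau_act"].voltages)
    tau_act = list(pr5["tau_act"].values)
    if pr2 is not None:
        tau_act_v.append(pr2[0])
        tau_act.append(pr2[1])

    tau_inact_v = np.concatenate([pr5["tau_inact"].voltages, pr4.voltages])
    tau_inact = np.concatenate([pr5["tau_inact"].values, pr4.values])

    return SummarySet(
        act_ss=act_ss,
        inact_ss=pr5["inact_ss"],
        tau_act=Curve(np.asarray(tau_act_v), np.asarray(tau_act)),
        tau_inact=Curve(tau_inact_v, tau_inact),
        iv=pr5["iv"],
    )
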