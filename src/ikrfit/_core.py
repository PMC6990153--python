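"""Compiled numerical kernels.

Two simulation routes are provided:

* an exact piecewise-analytic propagator for protocols made of constant
  voltage steps (each gate relaxes as a single exponential within a step);
* an adaptive Dormand-Prince 5(4) integrator with the standard 4th-order
  dense-output interpolant for arbitrary voltage commands (steps, sampled
  waveforms, sums of sines).  Segment boundaries act as forced restart
  points.

A third kernel, :func:`gate_recurrence`, runs the sequential part of the
Rush-Larsen exponential update used by the fast objective path.

Everything here is numba-compiled; the public API lives in
:mod:`ikrfit.simulate`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Segment kind codes shared with simulate.py
KIND_STEP = 0
KIND_SINE = 1
KIND_WAVEFORM = 2

_EXP_CLIP = 700.0


@njit(cache=True, inline="always")
def _rates(p, v):
    e1 = p[1] * v
    e2 = -p[3] * v
    e3 = p[5] * v
    e4 = -p[7] * v
    if e1 > _EXP_CLIP:
        e1 = _EXP_CLIP
    if e2 > _EXP_CLIP:
        e2 = _EXP_CLIP
    if e3 > _EXP_CLIP:
        e3 = _EXP_CLIP
    if e4 > _EXP_CLIP:
        e4 = _EXP_CLIP
    return (
        p[0] * np.exp(e1),
        p[2] * np.exp(e2),
        p[4] * np.exp(e3),
        p[6] * np.exp(e4),
    )


@njit(cache=True)
def simulate_steps(
    p,            # (8,) kinetic parameters
    g,            # conductance p9
    e_k,          # reversal potential (mV)
    dt,           # sample interval (ms)
    seg_v,        # (n_seg_total,) step voltages
    seg_dur,      # (n_seg_total,) step durations
    sweep_seg_lo, # (n_sweeps,) first segment index of each sweep
    sweep_seg_hi, # (n_sweeps,) one-past-last segment index
    sweep_n_out,  # (n_sweeps,) number of output samples per sweep
    sweep_out_lo, # (n_sweeps,) offset of each sweep in the output arrays
):
    """Exact analytic simulation of step protocols on a uniform grid.

    Gates start from the steady state at the first segment's voltage and
    carry across segments.  Returns (current, a, r) as flat arrays holding
    all sweeps back to back.
    """
    n_total = 0
    for s in range(len(sweep_n_out)):
        n_total += sweep_n_out[s]
    cur = np.empty(n_total)
    a_out = np.empty(n_total)
    r_out = np.empty(n_total)

    for s in range(len(sweep_seg_lo)):
        lo = sweep_seg_lo[s]
        hi = sweep_seg_hi[s]
        out0 = sweep_out_lo[s]
        n_out = sweep_n_out[s]

        k1, k2, k3, k4 = _rates(p, seg_v[lo])
        a = k1 / (k1 + k2)
        r = k4 / (k3 + k4)

        t0 = 0.0
        for j in range(lo, hi):
            v = seg_v[j]
            dur = seg_dur[j]
            k1, k2, k3, k4 = _rates(p, v)
            inv_ta = k1 + k2
            inv_tr = k3 + k4
            a_inf = k1 / inv_ta
            r_inf = k4 / inv_tr
            da = a - a_inf
            dr = r - r_inf
            drive = g * (v - e_k)

            i_start = int(np.ceil(t0 / dt - 1e-9))
            i_end = int(np.ceil((t0 + dur) / dt - 1e-9))
            if i_end > n_out:
                i_end = n_out
            if i_end > i_start:
                # exp(-(i dt - t0) k) advances by a constant factor per
                # sample, so one exponential per segment and gate suffices
                tt0 = i_start * dt - t0
                ea = np.exp(-tt0 * inv_ta)
                er = np.exp(-tt0 * inv_tr)
                qa = np.exp(-dt * inv_ta)
                qr = np.exp(-dt * inv_tr)
                for i in range(i_start, i_end):
                    ai = a_inf + da * ea
                    ri = r_inf + dr * er
                    a_out[out0 + i] = ai
                    r_out[out0 + i] = ri
                    cur[out0 + i] = drive * ai * ri
                    ea *= qa
                    er *= qr

            a = a_inf + da * np.exp(-dur * inv_ta)
            r = r_inf + dr * np.exp(-dur * inv_tr)
            t0 += dur

    return cur, a_out, r_out


@njit(cache=True, inline="always")
def _segment_voltage(
    j, t_loc, seg_kind, seg_v, sine_amp, sine_om, sine_ph, wf_t, wf_v, wf_lo, wf_hi
):
    kind = seg_kind[j]
    if kind == KIND_STEP:
        return seg_v[j]
    if kind == KIND_SINE:
        v = seg_v[j]
        for c in range(3):
            v += sine_amp[j, c] * np.sin(sine_om[j, c] * t_loc + sine_ph[j, c])
        return v
    # sampled waveform: linear interpolation with binary search
    lo = wf_lo[j]
    hi = wf_hi[j]
    if t_loc <= wf_t[lo]:
        return wf_v[lo]
    if t_loc >= wf_t[hi - 1]:
        return wf_v[hi - 1]
    left = lo
    right = hi - 1
    while right - left > 1:
        mid = (left + right) // 2
        if wf_t[mid] <= t_loc:
            left = mid
        else:
            right = mid
    frac = (t_loc - wf_t[left]) / (wf_t[right] - wf_t[left])
    return wf_v[left] + frac * (wf_v[right] - wf_v[left])


@njit(cache=True, inline="always")
def _rhs(p, v, a, r):
    k1, k2, k3, k4 = _rates(p, v)
    return k1 - (k1 + k2) * a, k4 - (k3 + k4) * r


@njit(cache=True)
def integrate_sweep(
    p,
    a0,
    r0,
    seg_kind,
    seg_v,
    seg_dur,
    sine_amp,
    sine_om,
    sine_ph,
    wf_t,
    wf_v,
    wf_lo,
    wf_hi,
    t_out,
    rtol,
    atol,
):
    """Adaptive Dormand-Prince 5(4) integration of one sweep.

    ``t_out`` holds sorted sweep-local sample times; gate values at those
    times are produced by the method's dense-output polynomial on accepted
    steps.  Returns (a_out, r_out, status); status 0 means success.
    """
    n_out = len(t_out)
    a_out = np.empty(n_out)
    r_out = np.empty(n_out)
    idx = 0

    a = a0
    r = r0
    t_seg_start = 0.0
    status = 0
    max_steps = 5_000_000
    steps = 0

    for j in range(len(seg_kind)):
        dur = seg_dur[j]
        # emit any samples that coincide with the segment start
        while idx < n_out and t_out[idx] <= t_seg_start + 1e-12:
            a_out[idx] = a
            r_out[idx] = r
            idx += 1

        t = 0.0  # segment-local time
        v = _segment_voltage(
            j, t, seg_kind, seg_v, sine_amp, sine_om, sine_ph, wf_t, wf_v, wf_lo, wf_hi
        )
        fa, fr = _rhs(p, v, a, r)
        h = dur if dur < 1.0 else 1.0

        while t < dur - 1e-12:
            if steps > max_steps:
                status = 1
                return a_out, r_out, status
            steps += 1
            if h > dur - t:
                h = dur - t

            # Dormand-Prince stages
            k1a, k1r = fa, fr

            v2 = _segment_voltage(
                j, t + 0.2 * h, seg_kind, seg_v, sine_amp, sine_om, sine_ph,
                wf_t, wf_v, wf_lo, wf_hi,
            )
            k2a, k2r = _rhs(p, v2, a + h * 0.2 * k1a, r + h * 0.2 * k1r)

            v3 = _segment_voltage(
                j, t + 0.3 * h, seg_kind, seg_v, sine_amp, sine_om, sine_ph,
                wf_t, wf_v, wf_lo, wf_hi,
            )
            k3a, k3r = _rhs(
                p, v3,
                a + h * (3.0 / 40.0 * k1a + 9.0 / 40.0 * k2a),
                r + h * (3.0 / 40.0 * k1r + 9.0 / 40.0 * k2r),
            )

            v4 = _segment_voltage(
                j, t + 0.8 * h, seg_kind, seg_v, sine_amp, sine_om, sine_ph,
                wf_t, wf_v, wf_lo, wf_hi,
            )
            k4a, k4r = _rhs(
                p, v4,
                a + h * (44.0 / 45.0 * k1a - 56.0 / 15.0 * k2a + 32.0 / 9.0 * k3a),
                r + h * (44.0 / 45.0 * k1r - 56.0 / 15.0 * k2r + 32.0 / 9.0 * k3r),
            )

            v5 = _segment_voltage(
                j, t + 8.0 / 9.0 * h, seg_kind, seg_v, sine_amp, sine_om, sine_ph,
                wf_t, wf_v, wf_lo, wf_hi,
            )
            k5a, k5r = _rhs(
                p, v5,
                a + h * (
                    19372.0 / 6561.0 * k1a - 25360.0 / 2187.0 * k2a
                    + 64448.0 / 6561.0 * k3a - 212.0 / 729.0 * k4a
                ),
                r + h * (
                    19372.0 / 6561.0 * k1r - 25360.0 / 2187.0 * k2r
                    + 64448.0 / 6561.0 * k3r - 212.0 / 729.0 * k4r
                ),
            )

            v6 = _segment_voltage(
                j, t + h, seg_kind, seg_v, sine_amp, sine_om, sine_ph,
                wf_t, wf_v, wf_lo, wf_hi,
            )
            k6a, k6r = _rhs(
                p, v6,
                a + h * (
                    9017.0 / 3168.0 * k1a - 355.0 / 33.0 * k2a
                    + 46732.0 / 5247.0 * k3a + 49.0 / 176.0 * k4a
                    - 5103.0 / 18656.0 * k5a
                ),
                r + h * (
                    9017.0 / 3168.0 * k1r - 355.0 / 33.0 * k2r
                    + 46732.0 / 5247.0 * k3r + 49.0 / 176.0 * k4r
                    - 5103.0 / 18656.0 * k5r
                ),
            )

            a_new = a + h * (
                35.0 / 384.0 * k1a + 500.0 / 1113.0 * k3a + 125.0 / 192.0 * k4a
                - 2187.0 / 6784.0 * k5a + 11.0 / 84.0 * k6a
            )
            r_new = r + h * (
                35.0 / 384.0 * k1r + 500.0 / 1113.0 * k3r + 125.0 / 192.0 * k4r
                - 2187.0 / 6784.0 * k5r + 11.0 / 84.0 * k6r
            )

            fa_new, fr_new = _rhs(p, v6, a_new, r_new)

            # embedded 4th-order estimate (7th stage = FSAL derivative)
            a_low = a + h * (
                5179.0 / 57600.0 * k1a + 7571.0 / 16695.0 * k3a
                + 393.0 / 640.0 * k4a - 92097.0 / 339200.0 * k5a
                + 187.0 / 2100.0 * k6a + 1.0 / 40.0 * fa_new
            )
            r_low = r + h * (
                5179.0 / 57600.0 * k1r + 7571.0 / 16695.0 * k3r
                + 393.0 / 640.0 * k4r - 92097.0 / 339200.0 * k5r
                + 187.0 / 2100.0 * k6r + 1.0 / 40.0 * fr_new
            )

            sc_a = atol + rtol * max(abs(a), abs(a_new))
            sc_r = atol + rtol * max(abs(r), abs(r_new))
            err = np.sqrt(
                0.5 * (((a_new - a_low) / sc_a) ** 2 + ((r_new - r_low) / sc_r) ** 2)
            )

            if not np.isfinite(err):
                status = 1
                return a_out, r_out, status

            if err <= 1.0:
                # accept; emit samples inside (t, t+h] using the 4th-order
                # Dormand-Prince dense-output polynomial
                t_new = t + h
                while idx < n_out and t_out[idx] - t_seg_start <= t_new + 1e-12:
                    tq = t_out[idx] - t_seg_start
                    x1 = (tq - t) / h
                    x2 = x1 * x1
                    x3 = x2 * x1
                    x4 = x3 * x1
                    b1 = (
                        x1
                        - 8048581381.0 / 2820520608.0 * x2
                        + 8663915743.0 / 2820520608.0 * x3
                        - 12715105075.0 / 11282082432.0 * x4
                    )
                    b3 = (
                        131558114200.0 / 32700410799.0 * x2
                        - 68118460800.0 / 10900136933.0 * x3
                        + 87487479700.0 / 32700410799.0 * x4
                    )
                    b4 = (
                        -1754552775.0 / 470086768.0 * x2
                        + 14199869525.0 / 1410260304.0 * x3
                        - 10690763975.0 / 1880347072.0 * x4
                    )
                    b5 = (
                        127303824393.0 / 49829197408.0 * x2
                        - 318862633887.0 / 49829197408.0 * x3
                        + 701980252875.0 / 199316789632.0 * x4
                    )
                    b6 = (
                        -282668133.0 / 205662961.0 * x2
                        + 2019193451.0 / 616988883.0 * x3
                        - 1453857185.0 / 822651844.0 * x4
                    )
                    b7 = (
                        40617522.0 / 29380423.0 * x2
                        - 110615467.0 / 29380423.0 * x3
                        + 69997945.0 / 29380423.0 * x4
                    )
                    a_out[idx] = a + h * (
                        b1 * k1a + b3 * k3a + b4 * k4a
                        + b5 * k5a + b6 * k6a + b7 * fa_new
                    )
                    r_out[idx] = r + h * (
                        b1 * k1r + b3 * k3r + b4 * k4r
                        + b5 * k5r + b6 * k6r + b7 * fr_new
                    )
                    idx += 1
                t = t_new
                a = a_new
                r = r_new
                fa = fa_new
                fr = fr_new
                fac = 0.9 * err ** -0.2 if err > 0.0 else 5.0
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                fac = 0.9 * err ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h *= fac
                if h < 1e-12:
                    status = 1
                    return a_out, r_out, status

        t_seg_start += dur

    # samples at (or numerically beyond) the sweep end
    while idx < n_out:
        a_out[idx] = a
        r_out[idx] = r
        idx += 1

    return a_out, r_out, status


@njit(cache=True)
def gate_recurrence(x0, x_inf, decay):
    """Sequential exponential gate update on a uniform grid.

    ``out[0] = x0``; ``out[i] = x_inf[i] + (out[i-1] - x_inf[i]) * decay[i]``.
    The per-interval tables (steady state and decay factor at the interval
    midpoint voltage) are precomputed vectorized by the caller, so this loop
    is pure multiply-add.
    """
    n = x_inf.size
    out = np.empty(n)
    x = x0
    out[0] = x0
    for i in range(1, n):
        x = x_inf[i] + (x - x_inf[i]) * decay[i]
        out[i] = x
    return out


def warm_up() -> None:
    """Trigger JIT compilation of the kernels with a tiny problem."""
    p = np.full(8, 1e-2)
    simulate_steps(
        p, 1.0, -88.0, 1.0,
        np.array([-80.0, 40.0]), np.array([5.0, 5.0]),
        np.array([0]), np.array([2]), np.array([10]), np.array([0]),
    )
    integrate_sweep(
        p, 0.5, 0.5,
        np.array([KIND_STEP, KIND_SINE], dtype=np.int64),
        np.array([-80.0, -30.0]),
        np.array([5.0, 5.0]),
        np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((2, 3)),
        np.zeros(2), np.zeros(2),
        np.zeros(2, dtype=np.int64), np.zeros(2, dtype=np.int64),
        np.arange(10) * 1.0, 1e-8, 1e-8,
    )
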