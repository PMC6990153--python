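"""Synthetic-cell generation with known ground truth.

A synthetic cell is built by simulating every protocol with a known
parameter set, adding iid Gaussian noise to the current samples, and
running the standard summary extraction on the noisy traces.  The noise
level defaults to a fraction of the noiseless sinusoidal-protocol current
range, chosen to resemble the strongest noise seen in real whole-cell
recordings.  Everything is determined by the seed.

A deterministic generator for an action-potential-like waveform train is
included as a stand-in validation protocol: a handful of AP morphologies
(short, long, and an early-afterdepolarization-like pathological variant)
on a resting baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .model import IonicConditions, ModelParameters
from .objectives import CellDataset
from .protocols import Protocol, Waveform, build_default_protocols
from .simulate import simulate_ode, simulate_step
from .summarize import assemble_summary

__all__ = [
    "SyntheticSpec",
    "default_params",
    "default_conditions",
    "default_fixture",
    "sample_plausible_params",
    "generate_ap_waveform",
    "generate_cell",
]

STEP_PROTOCOLS = ("Pr2", "Pr3", "Pr4", "Pr5")


def _fixture_payload() -> dict:
    from importlib import resources

    with resources.files("ikrfit.data").joinpath("default_params.json").open() as fh:
        return json.load(fh)


def default_params() -> ModelParameters:
    """The package's documented default parameter set."""
    return ModelParameters.from_dict(_fixture_payload()["params"])


def default_conditions() -> IonicConditions:
    cfg = _fixture_payload()["conditions"]
    return IonicConditions(cfg["K_out"], cfg["K_in"], cfg["T"])


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic cell."""

    true_params: ModelParameters
    conditions: IonicConditions
    seed: int = 0
    noise_sigma: Optional[float] = None  # absolute, in current units
    noise_fraction: float = 0.01         # of the noiseless Pr7 range, if sigma None
    include: Sequence[str] = ("Pr2", "Pr3", "Pr4", "Pr5", "Pr6", "Pr7")

    def __post_init__(self):
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def default_fixture(seed: int = 0, **overrides) -> SyntheticSpec:
    """Default synthetic-cell recipe built from the shipped parameter set."""
    payload = _fixture_payload()
    return SyntheticSpec(
        true_params=default_params(),
        conditions=default_conditions(),
        seed=seed,
        noise_fraction=float(payload.get("noise_fraction", 0.01)),
        **overrides,
    )


def sample_plausible_params(
    rng: np.random.Generator,
    spread: float = 1.4,
    bounds=None,
) -> ModelParameters:
    """A random in-bounds parameter set with physiological kinetics.

    Each default-fixture parameter is multiplied by a log-uniform factor in
    ``[1/spread, spread]``; draws violating the search constraints are
    rejected.  (Uniform draws over the full constraint box routinely give
    kinetics the protocols cannot resolve — gates switching far outside the
    probed voltage range — so recovery experiments use this sampler.)
    """
    from .optimize import default_bounds, in_bounds

    bounds = bounds if bounds is not None else default_bounds()
    base = default_params().as_array()
    log_spread = np.log(spread)
    for _ in range(1000):
        factors = np.exp(rng.uniform(-log_spread, log_spread, size=9))
        theta = base * factors
        if in_bounds(theta, bounds):
            return ModelParameters.from_array(theta)
    raise RuntimeError("could not sample an in-bounds parameter set")


# ---------------------------------------------------------------------------
# AP-like waveform generation


def _ap_shape(t, apd: float, peak: float, rest: float, ead: bool):
    """One action-potential morphology starting at local time 0."""
    upstroke = 1.5  # ms
    v = np.full(t.shape, rest)
    rising = t < upstroke
    v[rising] = rest + (peak - rest) * (t[rising] / upstroke)
    after = ~rising
    ta = t[after] - upstroke
    dome = (peak - rest) * np.exp(-ta / (1.8 * apd))
    repol = 1.0 / (1.0 + np.exp((ta - apd) / (0.06 * apd)))
    shape = dome * repol
    if ead:
        bump = 18.0 * np.exp(-(((ta - 0.85 * apd) / (0.08 * apd)) ** 2))
        shape = shape + bump
    v[after] = rest + shape
    return v


def generate_ap_waveform(
    seed: int = 0,
    dt_nodes: float = 1.0,
    rest: float = -80.0,
    config: Optional[dict] = None,
) -> Protocol:
    """Deterministic train of AP-like waveforms as a sampled protocol.

    Morphologies: a short and a long "healthy" AP plus an EAD-like
    pathological variant, separated by diastolic intervals.  The seed
    applies small jitters so that distinct validation sets can be built.
    """
    rng = np.random.default_rng(seed)
    config = config or {}
    beats = config.get(
        "beats",
        [
            {"apd": 250.0, "peak": 42.0, "ead": False, "gap": 600.0},
            {"apd": 380.0, "peak": 40.0, "ead": False, "gap": 700.0},
            {"apd": 500.0, "peak": 38.0, "ead": True, "gap": 800.0},
            {"apd": 300.0, "peak": 41.0, "ead": False, "gap": 900.0},
        ],
    )
    lead_in = config.get("lead_in", 500.0)

    total = lead_in + sum(b["apd"] * 2.0 + b["gap"] for b in beats)
    n = int(np.ceil(total / dt_nodes)) + 1
    t = np.arange(n) * dt_nodes
    v = np.full(n, rest)

    start = lead_in
    for beat in beats:
        apd = beat["apd"] * (1.0 + 0.03 * rng.standard_normal())
        peak = beat["peak"] + rng.uniform(-1.0, 1.0)
        span = apd * 2.0
        sel = (t >= start) & (t < start + span)
        v[sel] = _ap_shape(t[sel] - start, apd, peak, rest, beat["ead"])
        start += span + beat["gap"]

    v = np.clip(v, -120.0, 60.0)
    segment = Waveform(duration=float(t[-1]), times=t, voltages=v)
    return Protocol("Pr6", [[segment]], dt=0.1, meta={"roles": ["waveform"]})


# ---------------------------------------------------------------------------
# Cell generation


def noiseless_pr7_range(
    params: ModelParameters,
    conditions: IonicConditions,
    protocol_pr7: Protocol,
    dt: Optional[float] = None,
) -> float:
    traces = simulate_ode(params, protocol_pr7, conditions, dt)
    return float(np.ptp(np.concatenate([t.currents for t in traces])))


def generate_cell(
    spec: SyntheticSpec,
    protocols: Optional[Dict[str, Protocol]] = None,
    dt: Union[float, Dict[str, float], None] = None,
    cell_id: Optional[str] = None,
) -> CellDataset:
    """Simulate, add noise, and summarize one synthetic cell.

    Step protocols use the analytic solver, the waveform/sine protocols the
    ODE solver.  The summary curves are computed from the *noisy* traces,
    exactly as they would be for a real recording.  ``dt`` may be a single
    sample interval or a per-protocol mapping (key ``"default"`` for the
    rest).
    """
    if protocols is None:
        protocols = build_default_protocols()
        protocols["Pr6"] = generate_ap_waveform(seed=spec.seed)
    rng = np.random.default_rng(spec.seed)

    if isinstance(dt, dict):
        dt_for = lambda name: dt.get(name, dt.get("default"))
    else:
        dt_for = lambda name: dt

    sigma = spec.noise_sigma
    if sigma is None:
        if "Pr7" not in protocols:
            raise ValueError("need Pr7 to set the default noise level")
        sigma = spec.noise_fraction * noiseless_pr7_range(
            spec.true_params, spec.conditions, protocols["Pr7"], dt_for("Pr7")
        )

    traces: Dict[str, list] = {}
    for name in spec.include:
        protocol = protocols[name]
        if protocol.is_step_protocol():
            clean = simulate_step(
                spec.true_params, protocol, spec.conditions, dt_for(name)
            )
        else:
            clean = simulate_ode(
                spec.true_params, protocol, spec.conditions, dt_for(name)
            )
        noisy = []
        for trace in clean:
            noise = rng.normal(0.0, sigma, trace.currents.size) if sigma > 0 else 0.0
            noisy.append(trace.with_currents(trace.currents + noise))
        traces[name] = noisy

    summary = None
    if all(name in traces for name in STEP_PROTOCOLS):
        summary = assemble_summary(
            {k: traces[k] for k in STEP_PROTOCOLS}, protocols, spec.conditions.E_K
        )

    return CellDataset(
        cell_id=cell_id or f"synthetic-{spec.seed}",
        traces=traces,
        summary=summary,
        conditions=spec.conditions,
        meta={
            "true_params": spec.true_params.to_dict(),
            "noise_sigma": sigma,
            "seed": spec.seed,
        },
    )
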