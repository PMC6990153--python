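"""Evaluation harness: fit all methods to cells, validate, cross-compare.

Produces the relative-RMSE cross-validation table (one row per error
measure, one column per fitting method, each row scaled so the best method
scores exactly 1) and per-method reliability fractions from the multi-start
repeats.  A master-seed scheme derives a separate seed for every
(cell, method) pair, and each repeat inside a multi-start gets its own
spawned seed, so any single repeat can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .method1 import Method1Error, method1_fit
from .model import IonicConditions, ModelParameters
from .objectives import (
    CellDataset,
    e_ap,
    e_m1,
    e_m2,
    e_m3,
    e_m4,
    make_e_m2_objective,
    make_e_m3_objective,
    make_e_m4_objective,
)
from .optimize import (
    FitResult,
    OptimizerConfig,
    ParameterBounds,
    SearchTransform,
    default_bounds,
    multi_start,
    reliability,
)
from .protocols import (
    Protocol,
    build_default_protocols,
    load_sampled_protocol,
    write_sampled_protocol,
)
from .simulate import Trace, read_trace, write_trace
from .summarize import SummarySet

__all__ = [
    "StudyConfig",
    "cross_validate",
    "aggregate_cells",
    "run_study",
    "scan_objective",
    "save_cell",
    "load_cell",
]

logger = logging.getLogger(__name__)

MEASURE_ROWS = ("E_AP", "E_M1", "E_M2", "E_M3", "E_M4")


@dataclass
class StudyConfig:
    """Study-level knobs.  ``repeats`` holds the full-size repeat counts
    (80 for the simulated-summary method, 50 for the whole-trace methods);
    ``repeats_scale`` shrinks them for desk-scale runs."""

    methods: Sequence[int] = (1, 2, 3, 4)
    repeats: Dict[int, int] = field(default_factory=lambda: {2: 80, 3: 50, 4: 50})
    repeats_scale: float = 1.0
    seed: int = 0
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    bounds: Optional[ParameterBounds] = None
    transform: SearchTransform = field(default_factory=SearchTransform.default)
    fit_dt: Optional[float] = None  # simulation dt used inside objectives

    def n_repeats(self, method: int) -> int:
        return max(1, int(round(self.repeats[method] * self.repeats_scale)))


def _method_seed(master: int, cell_index: int, method: int) -> int:
    seq = np.random.SeedSequence(entropy=master, spawn_key=(cell_index, method))
    return int(seq.generate_state(1)[0])


def cross_validate(
    cell: CellDataset,
    fits: Dict[str, ModelParameters],
    protocols: Dict[str, Protocol],
    dt: Optional[float] = None,
) -> pd.DataFrame:
    """Relative-RMSE table: rows are error measures, columns methods; each
    row is divided by its minimum so the best method shows exactly 1."""
    if not fits:
        raise ValueError("need at least one fitted parameter set")
    methods = sorted(fits)
    rows = {}
    for row in MEASURE_ROWS:
        if row == "E_AP" and not cell.has("Pr6"):
            continue
        values = []
        for m in methods:
            params = fits[m]
            try:
                if row == "E_AP":
                    v = e_ap(params, cell, protocols["Pr6"], dt)
                elif row == "E_M1":
                    v = e_m1(params, cell)
                elif row == "E_M2":
                    v = e_m2(params, cell, protocols, dt)
                elif row == "E_M3":
                    v = e_m3(params, cell, protocols, dt)
                else:
                    v = e_m4(params, cell, protocols["Pr7"], dt)
            except Exception as exc:
                logger.warning("%s evaluation failed for method %s: %s", row, m, exc)
                v = np.inf
            values.append(v)
        rows[row] = values
    table = pd.DataFrame(rows, index=methods).T

    def _relative(row):
        best = row.min()
        if best == 0.0:  # degenerate only on noiseless synthetic data
            return row.map(lambda v: 1.0 if v == best else np.inf)
        return row / best

    return table.apply(_relative, axis=1)


def aggregate_cells(
    tables: Sequence[pd.DataFrame],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Element-wise mean and standard deviation over per-cell tables."""
    if not tables:
        raise ValueError("need at least one table")
    stack = np.stack([t.to_numpy(float) for t in tables])
    mean = pd.DataFrame(stack.mean(axis=0), index=tables[0].index,
                        columns=tables[0].columns)
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), index=tables[0].index,
                      columns=tables[0].columns)
    return mean, sd


def _fit_cell(
    cell: CellDataset,
    protocols: Dict[str, Protocol],
    config: StudyConfig,
    cell_index: int,
):
    bounds = config.bounds if config.bounds is not None else default_bounds()
    fits: Dict[str, ModelParameters] = {}
    all_results: Dict[str, List[FitResult]] = {}
    rel: Dict[str, Tuple[float, float]] = {}

    if 1 in config.methods:
        try:
            fits["1"] = method1_fit(
                cell.summary, protocols["Pr5"], cell.conditions, config.fit_dt
            )
        except Method1Error as exc:
            logger.warning("cell %s: direct fit failed: %s", cell.cell_id, exc)

    factories = {
        2: lambda: make_e_m2_objective(cell, protocols, config.fit_dt),
        3: lambda: make_e_m3_objective(cell, protocols, config.fit_dt),
        4: lambda: make_e_m4_objective(cell, protocols["Pr7"], config.fit_dt),
    }
    for method in (2, 3, 4):
        if method not in config.methods:
            continue
        objective = factories[method]()
        seed = _method_seed(config.seed, cell_index, method)
        results, best = multi_start(
            objective, bounds, config.transform, config.optimizer,
            n_repeats=config.n_repeats(method), seed=seed, method=str(method),
        )
        fits[str(method)] = best.params
        all_results[str(method)] = results
        rel[str(method)] = reliability(results)
    return fits, all_results, rel


def run_study(
    cells: Sequence[CellDataset],
    protocols: Optional[Dict[str, Protocol]] = None,
    config: Optional[StudyConfig] = None,
) -> dict:
    """Fit every requested method to every cell, cross-validate, and
    aggregate.  Per-cell failures are isolated and reported; the study
    continues with the remaining cells."""
    config = config or StudyConfig()
    if protocols is None:
        protocols = build_default_protocols()

    report: dict = {"cells": {}, "config": {"seed": config.seed,
                                            "methods": list(config.methods),
                                            "repeats_scale": config.repeats_scale}}
    tables = []
    for index, cell in enumerate(cells):
        try:
            fits, results, rel = _fit_cell(cell, protocols, config, index)
            table = cross_validate(cell, fits, protocols, config.fit_dt)
            tables.append(table)
            report["cells"][cell.cell_id] = {
                "fits": {m: p.to_dict() for m, p in fits.items()},
                "reliability": {
                    m: {"frac_rmse_close": r[0], "frac_param_close": r[1]}
                    for m, r in rel.items()
                },
                "results": {
                    m: [r.to_dict() for r in rs] for m, rs in results.items()
                },
                "cross_validation": table.to_dict(),
            }
        except Exception as exc:
            logger.exception("cell %s failed", cell.cell_id)
            report["cells"][cell.cell_id] = {"error": str(exc)}
    if tables:
        mean, sd = aggregate_cells(tables)
        report["aggregate"] = {"mean": mean.to_dict(), "sd": sd.to_dict()}
    return report


def save_report(report: dict, out_dir: Union[str, Path]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    if "aggregate" in report:
        pd.DataFrame(report["aggregate"]["mean"]).to_csv(out / "crossval_mean.csv")
        pd.DataFrame(report["aggregate"]["sd"]).to_csv(out / "crossval_sd.csv")
    rows = []
    for cell_id, payload in report["cells"].items():
        for m, r in payload.get("reliability", {}).items():
            rows.append({"cell": cell_id, "method": m, **r})
    if rows:
        pd.DataFrame(rows).to_csv(out / "reliability.csv", index=False)


def scan_objective(
    objective,
    center: ModelParameters,
    i: int,
    j: int,
    span: float = 2.0,
    n: int = 21,
    log_axes: bool = True,
) -> pd.DataFrame:
    """Two-dimensional slice of an objective around a point: parameters
    ``i`` and ``j`` (0-based) swept over ``center/span .. center*span``
    (log axes) or ±span (linear), others held fixed."""
    theta0 = center.as_array()
    if log_axes:
        grid_i = theta0[i] * np.exp(np.linspace(-np.log(span), np.log(span), n))
        grid_j = theta0[j] * np.exp(np.linspace(-np.log(span), np.log(span), n))
    else:
        grid_i = theta0[i] + np.linspace(-span, span, n)
        grid_j = theta0[j] + np.linspace(-span, span, n)
    records = []
    for vi in grid_i:
        for vj in grid_j:
            theta = theta0.copy()
            theta[i], theta[j] = vi, vj
            try:
                value = objective(ModelParameters.from_array(theta))
            except Exception:
                value = np.inf
            records.append({"p_i": vi, "p_j": vj, "value": value})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Cell directory I/O (shared layout for synthetic and real data)


def save_cell(cell: CellDataset, out_dir: Union[str, Path],
              protocols: Optional[Dict[str, Protocol]] = None) -> None:
    """Write a cell directory: per-sweep trace CSVs, summary curves,
    ionic conditions, and any metadata (including synthetic ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, traces in cell.traces.items():
        for trace in traces:
            write_trace(trace, out / f"{name}_sweep{trace.sweep:02d}.csv")
    if cell.summary is not None:
        cell.summary.save(out / "summary.csv")
    (out / "conditions.json").write_text(json.dumps({
        "K_out": cell.conditions.K_out,
        "K_in": cell.conditions.K_in,
        "T": cell.conditions.T,
    }, indent=2))
    if cell.meta:
        (out / "meta.json").write_text(json.dumps(cell.meta, indent=2, default=float))
    if protocols and "Pr6" in protocols:
        write_sampled_protocol(protocols["Pr6"], out / "pr6_waveform.txt")


def load_cell(cell_dir: Union[str, Path]) -> CellDataset:
    """Read a cell directory written by :func:`save_cell` (or real data
    arranged in the same layout)."""
    path = Path(cell_dir)
    cfg = json.loads((path / "conditions.json").read_text())
    conditions = IonicConditions(cfg["K_out"], cfg["K_in"], cfg["T"])
    traces: Dict[str, List[Trace]] = {}
    for file in sorted(path.glob("Pr*_sweep*.csv")):
        trace = read_trace(file)
        traces.setdefault(trace.protocol, []).append(trace)
    for name in traces:
        traces[name].sort(key=lambda t: t.sweep)
    summary = None
    if (path / "summary.csv").exists():
        summary = SummarySet.load(path / "summary.csv")
    meta = {}
    if (path / "meta.json").exists():
        meta = json.loads((path / "meta.json").read_text())
    return CellDataset(
        cell_id=path.name, traces=traces, summary=summary,
        conditions=conditions, meta=meta,
    )


def load_cell_protocols(cell_dir: Union[str, Path]) -> Dict[str, Protocol]:
    """Default protocols, plus the cell's own Pr6 waveform when present."""
    protocols = build_default_protocols()
    wf = Path(cell_dir) / "pr6_waveform.txt"
    if wf.exists():
        protocols["Pr6"] = load_sampled_protocol(wf, name="Pr6")
    return protocols
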