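# ikrfit

Fitting a two-gate Hodgkin–Huxley model of the rapid delayed-rectifier
potassium current (IKr/hERG) to whole-cell voltage-clamp recordings.

The package implements four complete fitting routes and the machinery to
compare them:

1. **Direct summary-curve fit** — Boltzmann fits of the steady-state
   curves, log-linear regressions of the rates, algebraic
   back-substitution, and a single simulation to scale the conductance.
2. **Simulated summary-curve fit** — the step protocols are simulated and
   passed through the *identical* extraction pipeline as the data; the
   mismatch between simulated and experimental summary curves is minimized
   numerically.
3. **Whole-trace fit to conventional step protocols** (≈228 s of protocol
   per evaluation, simulated exactly with the analytic piecewise solution).
4. **Whole-trace fit to a short sum-of-sines protocol** (8 s per
   evaluation, adaptive ODE integration).

Fitted models are validated on an action-potential waveform protocol that
is never used in fitting, cross-validated on every other method's fitting
criterion, and checked for reliability across repeated multi-start
optimizations. A synthetic-data module generates complete cells (currents
plus iid Gaussian noise, plus a deterministic AP-like validation waveform)
with known ground truth, so the whole pipeline is testable offline.

## Layout

| module       | contents                                                        |
|--------------|-----------------------------------------------------------------|
| `model`      | transition rates, steady states/time constants, current, Nernst potential, analytic fixed-voltage solution |
| `protocols`  | Pr2–Pr7 protocol builders (grids in `data/protocols.yaml`), sampled-waveform I/O, capacitance-artifact mask (5 ms blanking) |
| `simulate`   | exact analytic step simulation, adaptive Dormand–Prince integration, trace CSV I/O |
| `summarize`  | the five summary curves: activation/inactivation steady states, both time constants, IV curve |
| `method1`    | the direct fit (Boltzmann + log-linear rates + conductance scaling), plus an optional numerical mode |
| `objectives` | the five error measures and fast objective factories for optimizers |
| `optimize`   | bounds (box + rate bands), log transforms, in-repo CMA-ES, multi-start, reliability fractions |
| `synthetic`  | synthetic-cell generator, default parameter fixture, AP-like waveform generator |
| `workbench`  | study harness: cross-validation tables, aggregation, cell-directory I/O, 2-D objective scans |

Units throughout: milliseconds, millivolts, rates in 1/ms; current in the
unit implied by the conductance (nA when the conductance is in µS).

## CLI

```sh
ikrfit protocol show Pr7                 # inspect a protocol
ikrfit synth --out cell0 --seed 1        # synthetic cell directory with known truth
ikrfit summarize --cell-dir cell0 --out summary.csv
ikrfit fit --method 4 --cell-dir cell0 --repeats 50 --seed 1 --out fit4.json
ikrfit score --method ap --params params.json --cell-dir cell0
ikrfit study --cells cells/ --out report/ --repeats-scale 0.1 --seed 1
ikrfit scan --method 4 --cell-dir cell0 --params params.json --pi 0 --pj 1 --out scan.csv
```

Cell directories hold one CSV per sweep (`Pr5_sweep03.csv` with columns
`time_ms, voltage_mV, current, keep`), `summary.csv`, `conditions.json`
(potassium concentrations and temperature, from which the reversal
potential is computed), and optionally `pr6_waveform.txt` (two-column
sampled validation waveform) — real recordings arranged in the same layout
are accepted by every command.

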