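"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda) CMA-ES with
rank-one and rank-mu covariance updates and cumulative step-size
adaptation, following Hansen's tutorial formulation.  Infeasible points may
be scored ``inf``; only ranks enter the update, so this is handled
naturally.  Deterministic given the random generator passed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CMAResult", "cmaes_minimize"]


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    n_iterations: int
    converged: bool


def cmaes_minimize(
    func: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    rng: np.random.Generator,
    popsize: int = 10,
    max_iter: int = 10_000,
    ftol: float = 1e-11,
    stall_iters: int = 200,
) -> CMAResult:
    """Minimize ``func`` starting from ``x0`` with initial step ``sigma0``.

    Stops when the best objective value changes by less than ``ftol`` per
    iteration for ``stall_iters`` successive iterations (converged=True),
    or after ``max_iter`` iterations.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    lam = int(popsize)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    inv_sqrt_C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)

    best_x = x0.copy()
    best_f = func(x0)
    n_eval = 1
    eigen_interval = max(1, int(1 / ((c1 + cmu) * n * 10)))

    stall = 0
    converged = False
    iteration = 0
    prev_best = best_f

    for iteration in range(1, max_iter + 1):
        Z = rng.standard_normal((lam, n))
        Y = Z @ (B * D).T  # y_k = B diag(D) z_k
        X = mean + sigma * Y
        f_vals = np.array([func(x) for x in X])
        n_eval += lam

        order = np.argsort(f_vals, kind="stable")
        if f_vals[order[0]] < best_f:
            best_f = float(f_vals[order[0]])
            best_x = X[order[0]].copy()

        if not np.isfinite(f_vals[order[0]]) and not np.isfinite(best_f):
            # entire population infeasible and no feasible point seen yet:
            # widen the search and try again
            sigma *= 1.5
            continue

        sel = X[order[:mu]]
        old_mean = mean
        mean = w @ sel
        shift = (mean - old_mean) / sigma

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (inv_sqrt_C @ shift)
        hsig = float(
            np.linalg.norm(ps)
            / np.sqrt(1 - (1 - cs) ** (2 * n_eval / lam))
            / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * shift

        art = (sel - old_mean) / sigma
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * art.T @ (w[:, None] * art)
        )
        sigma *= float(np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1)))
        if not np.isfinite(sigma) or sigma > 1e6:
            break

        if iteration % eigen_interval == 0:
            C = (C + C.T) / 2
            eigvals, B = np.linalg.eigh(C)
            eigvals = np.maximum(eigvals, 1e-30)
            D = np.sqrt(eigvals)
            inv_sqrt_C = B @ np.diag(1.0 / D) @ B.T

        iter_best = float(f_vals[order[0]])
        change = abs(prev_best - iter_best)
        prev_best = iter_best
        if np.isfinite(iter_best) and change < ftol:
            stall += 1
            if stall >= stall_iters:
                converged = True
                break
        else:
            stall = 0

    return CMAResult(
        x=best_x,
        fun=float(best_f),
        n_evaluations=n_eval,
        n_iterations=iteration,
        converged=converged,
    )
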