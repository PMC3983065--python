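"""Covariance-matrix-adaptation evolution strategy (CMA-ES), minimization.

Self-contained (μ/μ_w, λ) CMA-ES with rank-one and rank-μ covariance
updates and cumulative step-size adaptation, following Hansen's standard
tutorial formulation.  Box constraints are handled by projecting sampled
candidates onto the box and adding a quadratic penalty on the projection
distance, so the objective is only ever evaluated at feasible points.

This is deliberately minimal — no separable/large-scale variants, no noise
handling — and is deterministic given a seed.  It is sufficient for the
6-dimensional threshold-model fits this package performs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["CMAResult", "cma_minimize"]


@dataclass
class CMAResult:
    x: np.ndarray            # best-ever feasible point
    fun: float               # its objective value
    n_evals: int
    n_restarts: int
    history: list            # (eval_count, best_f) per generation


def cma_minimize(
    fun: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    seed: int,
    popsize: int = 16,
    max_evals: int = 3000,
    sigma0_frac: float = 0.3,
    restarts: int = 2,
    x0: Optional[np.ndarray] = None,
    tol_fun: float = 1e-10,
    f_target: Optional[float] = None,
) -> CMAResult:
    """Minimize ``fun`` over a box.

    Parameters
    ----------
    fun : callable
        Objective; evaluated only at points inside the box.
    bounds : sequence of (low, high)
        Box constraints; the search is conducted in box-normalized [0, 1]
        coordinates.
    seed : int
        Seed for all sampling; runs are reproducible.
    popsize : int
        Candidates per generation (λ).
    max_evals : int
        Total objective-evaluation budget across restarts.
    sigma0_frac : float
        Initial step size as a fraction of the (normalized) box width.
    restarts : int
        Additional independent starts after the first run stalls or
        converges, keeping the best-ever solution.
    x0 : array, optional
        Initial mean for the first run (box midpoint if omitted).
    f_target : float, optional
        Stop as soon as the best objective value reaches this target.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy low < high")
    n = lo.size
    rng = np.random.default_rng(seed)

    def denorm(z):
        return lo + z * (hi - lo)

    # strategy constants (Hansen 2016 defaults)
    lam = max(popsize, 4)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w ** 2)
    c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    best_x = None
    best_f = np.inf
    evals = 0
    history: list = []
    runs = 0

    while (evals < max_evals and runs <= restarts
           and not (f_target is not None and best_f <= f_target)):
        runs += 1
        if x0 is not None and runs == 1:
            m = (np.asarray(x0, float) - lo) / (hi - lo)
        else:
            m = rng.uniform(0.25, 0.75, n) if runs > 1 else np.full(n, 0.5)
        sigma = sigma0_frac
        C = np.eye(n)
        p_sigma = np.zeros(n)
        p_c = np.zeros(n)
        eigen_ok = True
        B = np.eye(n)
        D = np.ones(n)
        stall = 0
        prev_best = np.inf

        while evals < max_evals:
            if not eigen_ok:
                C = (C + C.T) / 2
                d2, B = np.linalg.eigh(C)
                D = np.sqrt(np.maximum(d2, 1e-20))
                eigen_ok = True
            Z = rng.standard_normal((lam, n))
            Y = Z * D @ B.T                      # y ~ N(0, C)
            X = m + sigma * Y
            Xf = np.clip(X, 0.0, 1.0)
            f = np.empty(lam)
            for k in range(lam):
                pen = np.sum((X[k] - Xf[k]) ** 2)
                f[k] = fun(denorm(Xf[k])) + 1e3 * pen
                evals += 1
            order = np.argsort(f)
            gen_best = f[order[0]]
            if gen_best < best_f:
                best_f = gen_best
                best_x = denorm(Xf[order[0]]).copy()
            history.append((evals, best_f))

            y_w = w @ Y[order[:mu]]
            m = m + sigma * y_w
            # step-size path uses C^(-1/2) y_w
            c_inv_half_y = B @ ((B.T @ y_w) / D)
            p_sigma = ((1 - c_sigma) * p_sigma
                       + np.sqrt(c_sigma * (2 - c_sigma) * mu_eff) * c_inv_half_y)
            sigma *= np.exp((c_sigma / d_sigma)
                            * (np.linalg.norm(p_sigma) / chi_n - 1))
            h_sigma = (np.linalg.norm(p_sigma)
                       / np.sqrt(1 - (1 - c_sigma) ** (2 * len(history)))
                       < (1.4 + 2 / (n + 1)) * chi_n)
            p_c = ((1 - c_c) * p_c
                   + h_sigma * np.sqrt(c_c * (2 - c_c) * mu_eff) * y_w)
            rank_mu = (Y[order[:mu]].T * w) @ Y[order[:mu]]
            C = ((1 - c_1 - c_mu) * C
                 + c_1 * (np.outer(p_c, p_c)
                          + (not h_sigma) * c_c * (2 - c_c) * C)
                 + c_mu * rank_mu)
            eigen_ok = False

            # restart triggers: flat fitness or collapsed/exploded step
            if prev_best - gen_best < tol_fun:
                stall += 1
            else:
                stall = 0
            prev_best = min(prev_best, gen_best)
            if f_target is not None and best_f <= f_target:
                break
            if stall >= 20 or sigma < 1e-9 or sigma > 1e4:
                break

    return CMAResult(x=best_x, fun=float(best_f), n_evals=evals,
                     n_restarts=runs - 1, history=history)
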