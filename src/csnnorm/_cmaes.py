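"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

Standard (mu/mu_w, lambda) CMA-ES with rank-one and rank-mu covariance
updates and cumulative step-size adaptation, following Hansen's reference
formulation.  Box constraints are handled by clipping candidates to the box
before evaluation; the clipped vectors are also used in the distribution
update (simple and adequate for the mildly-bounded problems here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CMAESResult", "default_population_size", "cma_es_minimize"]


def default_population_size(n_params: int) -> int:
    """Hansen's default lambda = 4 + floor(3 ln N)."""
    return 4 + int(np.floor(3.0 * np.log(n_params)))


@dataclass
class CMAESResult:
    best_x: np.ndarray
    best_f: float
    history: list  # best-so-far objective after each generation
    n_evaluations: int


def cma_es_minimize(fun, x0, sigma0: float, bounds, max_generations: int,
                    popsize: int | None = None, seed: int = 0,
                    callback=None) -> CMAESResult:
    """Minimize ``fun`` over a box, starting the search distribution at x0.

    ``bounds`` is ``(lower, upper)`` (scalars or length-N arrays).  ``x0``
    itself is evaluated first, so the returned best is never worse than the
    starting point; a non-finite objective at x0 raises.
    """
    mean = np.asarray(x0, dtype=float).copy()
    n = mean.size
    lo = np.broadcast_to(np.asarray(bounds[0], dtype=float), (n,))
    hi = np.broadcast_to(np.asarray(bounds[1], dtype=float), (n,))
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    lam = popsize if popsize is not None else default_population_size(n)
    if lam < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(seed)

    f0 = float(fun(np.clip(mean, lo, hi)))
    if not np.isfinite(f0):
        raise ValueError("objective is not finite at the initial point")
    best_x = np.clip(mean, lo, hi).copy()
    best_f = f0
    n_eval = 1

    # selection and recombination weights
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    # adaptation constants
    cc = (4.0 + mueff / n) / (n + 4.0 + 2.0 * mueff / n)
    cs = (mueff + 2.0) / (n + mueff + 5.0)
    c1 = 2.0 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1.0 - c1, 2.0 * (mueff - 2.0 + 1.0 / mueff) / ((n + 2.0) ** 2 + mueff))
    damps = 1.0 + 2.0 * max(0.0, np.sqrt((mueff - 1.0) / (n + 1.0)) - 1.0) + cs
    chi_n = np.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n**2))

    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    sigma = float(sigma0)
    history: list = []

    for gen in range(1, max_generations + 1):
        # sample, clip to the box, evaluate
        eigvals, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(eigvals, 1e-20))
        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T  # y_i ~ N(0, C)
        x = np.clip(mean + sigma * y, lo, hi)
        f = np.array([float(fun(xi)) for xi in x])
        n_eval += lam

        order = np.argsort(f, kind="stable")
        if f[order[0]] < best_f:
            best_f = float(f[order[0]])
            best_x = x[order[0]].copy()
        history.append(best_f)

        x_sel = x[order[:mu]]
        y_sel = (x_sel - mean) / sigma  # post-clip steps
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        inv_sqrt_C = (B / D) @ B.T
        ps = (1.0 - cs) * ps + np.sqrt(cs * (2.0 - cs) * mueff) * (inv_sqrt_C @ y_w)
        hsig = (
            np.linalg.norm(ps) / np.sqrt(1.0 - (1.0 - cs) ** (2.0 * gen)) / chi_n
            < 1.4 + 2.0 / (n + 1.0)
        )
        pc = (1.0 - cc) * pc + hsig * np.sqrt(cc * (2.0 - cc) * mueff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1.0 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1.0 - hsig) * cc * (2.0 - cc) * C)
            + cmu * rank_mu
        )
        C = (C + C.T) / 2.0
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1.0))

        if callback is not None:
            callback(gen, best_f)

    return CMAESResult(best_x=best_x, best_f=best_f, history=history,
                       n_evaluations=n_eval)
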