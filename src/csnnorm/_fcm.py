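"""Fuzzy c-means clustering (Bezdek's alternating-optimization algorithm).

Minimizes sum_ij u_ij^m ||x_i - c_j||^2 subject to rows of U summing to 1,
by alternating the closed-form membership and center updates.  Euclidean
distance, seeded random membership initialization, deterministic given the
seed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["fuzzy_c_means"]


def fuzzy_c_means(data: np.ndarray, k: int, m: float = 2.0, seed: int = 0,
                  max_iter: int = 300, tol: float = 1e-6):
    """Cluster rows of ``data`` into ``k`` fuzzy clusters.

    Returns ``(membership, centers)`` where ``membership`` is (n, k) with
    rows summing to 1 and ``centers`` is (k, n_features).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (points x features)")
    n = data.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if m <= 1:
        raise ValueError("fuzziness exponent must be > 1")
    if k == 1:
        return np.ones((n, 1)), data.mean(axis=0, keepdims=True)

    rng = np.random.default_rng(seed)
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)
    exponent = -2.0 / (m - 1.0)
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ data) / um.sum(axis=0)[:, None]
        d = cdist(data, centers)
        zero = d == 0
        with np.errstate(divide="ignore"):
            inv = d**exponent
        u_new = inv / inv.sum(axis=1, keepdims=True)
        # points coinciding with a center: full membership there
        rows = zero.any(axis=1)
        if rows.any():
            u_new[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        shift = np.abs(u_new - u).max()
        u = u_new
        if shift < tol:
            break
    um = u**m
    centers = (um.T @ data) / um.sum(axis=0)[:, None]
    return u, centers
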