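"""Rank-to-reference baseline normalization.

A reference dataset defines a scale: its gene-wise mean sample, sorted
ascending.  Every sample of every other dataset is then rewritten so that
its r-th smallest entry takes the r-th value of the scale.  After this, all
samples contain exactly the same multiset of values — like quantile
normalization, except the target distribution is the reference's mean
sample rather than the mean of sorted samples.  The reference dataset
itself is left unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix

__all__ = ["ReferenceScale", "reference_scale", "rank_normalize"]


@dataclass(frozen=True)
class ReferenceScale:
    """Sorted (ascending) mean-sample values of the reference dataset."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values) < 0):
            raise ValueError("reference scale must be non-decreasing")

    def __len__(self) -> int:
        return self.values.size


def reference_scale(X_ref: ExpressionMatrix) -> ReferenceScale:
    """Gene-wise mean over samples, sorted ascending."""
    if X_ref.shape[0] == 0 or X_ref.shape[1] == 0:
        raise ValueError("reference matrix must be nonempty")
    means = X_ref.values.to_numpy().mean(axis=1)
    return ReferenceScale(np.sort(means))


def rank_normalize(Y: ExpressionMatrix, scale: ReferenceScale,
                   is_reference: bool = False) -> ExpressionMatrix:
    """Assign each entry the scale value matching its within-sample rank.

    Ranks are ordinal: ties are broken by gene row order (stable sort), so
    the result is deterministic.  When ``is_reference`` is set the matrix is
    returned as an unchanged copy (the reference is not transformed).
    """
    if is_reference:
        return Y.copy()
    vals = Y.values.to_numpy()
    if len(scale) != vals.shape[0]:
        raise ValueError(
            f"scale length {len(scale)} != gene count {vals.shape[0]}"
        )
    out = np.empty_like(vals, dtype=float)
    for s in range(vals.shape[1]):
        order = np.argsort(vals[:, s], kind="stable")
        out[order, s] = scale.values
    return Y.with_values(out)
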