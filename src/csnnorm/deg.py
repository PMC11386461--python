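"""Differential expression between two sample groups on log2 data.

The pipeline is deliberately simple and fully vectorized, since the CSN loss
re-runs it on every candidate transformation: a noise filter on raw log2
levels, a Welch two-sample t-test (unequal, unknown variances), FDR
estimation on the surviving p-values, and a log fold-change cutoff.  A gene
is differentially expressed when it passes the noise filter, q <= alpha and
|LFC| >= lfc_min; its direction is the sign of the LFC (+1 = higher in the
first group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, GroupDesign

__all__ = [
    "DEGConfig",
    "DEGList",
    "noise_filter",
    "welch_t_test",
    "estimate_fdr",
    "log_fold_change",
    "deg_table",
    "find_degs",
    "find_degs_between",
]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class DEGConfig:
    """Thresholds of the DEG pipeline.

    noise_threshold
        Log2 expression a sample must reach to count as "expressed"; a gene
        is kept when at least n samples reach it, where n is the size of the
        smallest group (default 4).
    fdr_alpha, lfc_min
        Significance and effect-size cutoffs (defaults 0.05 and 1).
    fdr_method
        "bh" (Benjamini-Hochberg, default) or "storey".
    pooled_noise
        Count qualifying samples pooled across both groups (default) or per
        group (gene kept when either group alone reaches n).
    zero_variance
        "error": zero-variance groups with different means raise;
        "floor": variances are floored at 1e-12 (useful for synthetic data).
    """

    noise_threshold: float = 4.0
    fdr_alpha: float = 0.05
    lfc_min: float = 1.0
    fdr_method: str = "bh"
    pooled_noise: bool = True
    zero_variance: str = "error"

    def __post_init__(self) -> None:
        if not np.isfinite(self.noise_threshold):
            raise ValueError("noise_threshold must be finite")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.fdr_method not in ("bh", "storey"):
            raise ValueError("fdr_method must be 'bh' or 'storey'")
        if self.zero_variance not in ("error", "floor"):
            raise ValueError("zero_variance must be 'error' or 'floor'")


@dataclass(frozen=True)
class DEGList:
    """A set of differentially expressed genes with per-gene direction.

    ``directions`` maps gene id -> +1/-1 where +1 means higher expression in
    the first of the two compared groups.  ``provenance`` names the two
    groups, first group first.
    """

    directions: dict
    provenance: tuple[str, str] = ("group1", "group2")

    @property
    def genes(self) -> frozenset:
        return frozenset(self.directions)

    @property
    def size(self) -> int:
        return len(self.directions)

    def subset(self, direction: int) -> frozenset:
        """Genes changing in the given direction (+1 or -1)."""
        return frozenset(g for g, d in self.directions.items() if d == direction)

    def flipped(self) -> "DEGList":
        return DEGList(
            {g: -d for g, d in self.directions.items()},
            (self.provenance[1], self.provenance[0]),
        )


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def noise_filter(values_g1, values_g2, config: DEGConfig = DEGConfig()) -> np.ndarray:
    """Per-gene keep flag: enough samples above the noise threshold.

    n is the size of the smaller group; by default qualifying samples are
    counted pooled across both groups.
    """
    a, b = _as_2d(values_g1), _as_2d(values_g2)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be nonempty")
    n = min(a.shape[1], b.shape[1])
    hits_a = (a >= config.noise_threshold).sum(axis=1)
    hits_b = (b >= config.noise_threshold).sum(axis=1)
    if config.pooled_noise:
        return hits_a + hits_b >= n
    return (hits_a >= n) | (hits_b >= n)


def welch_t_test(values_g1, values_g2, zero_variance: str = "error"):
    """Vectorized Welch t-test with Welch–Satterthwaite degrees of freedom.

    Returns (t, p) arrays (scalars for 1-D input).  Groups need >= 2 values.
    Rows where both groups are constant and equal get t = 0, p = 1.
    """
    a, b = _as_2d(values_g1), _as_2d(values_g2)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if zero_variance == "floor":
        v1 = np.maximum(v1, _VAR_FLOOR)
        v2 = np.maximum(v2, _VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    degenerate = se2 == 0
    if degenerate.any():
        if (degenerate & (diff != 0)).any():
            raise ValueError(
                "zero variance in both groups with unequal means; "
                "use zero_variance='floor' to continue"
            )
        # equal constant groups: define t = 0, p = 1
        se2 = np.where(degenerate, 1.0, se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    if np.asarray(values_g1).ndim == 1:
        return float(t[0]), float(p[0])
    return t, p


def _storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed pi0 estimate at a single lambda."""
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam))) if m else 1.0
    pi0 = max(pi0, 1.0 / m) if m else 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out


def estimate_fdr(pvalues, method: str = "bh") -> np.ndarray:
    """Per-gene q-values from raw p-values (Benjamini–Hochberg by default)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError(f"unknown FDR method {method!r}")


def log_fold_change(values_g1, values_g2) -> np.ndarray:
    """mean(group1) - mean(group2) on the log2 scale."""
    a, b = _as_2d(values_g1), _as_2d(values_g2)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be nonempty")
    lfc = a.mean(axis=1) - b.mean(axis=1)
    if np.asarray(values_g1).ndim == 1:
        return float(lfc[0])
    return lfc


def deg_table(values_g1: np.ndarray, values_g2: np.ndarray, gene_ids,
              config: DEGConfig = DEGConfig()) -> pd.DataFrame:
    """Full per-gene DEG table: lfc, p, q, keep flags and direction.

    The FDR is estimated over the noise-passing genes only (the filter runs
    before the test); filtered genes carry q = NaN.
    """
    a, b = _as_2d(values_g1), _as_2d(values_g2)
    gene_ids = np.asarray(gene_ids, dtype=object)
    if a.shape[0] != gene_ids.size or b.shape[0] != gene_ids.size:
        raise ValueError("gene_ids length must match the value arrays")
    keep = noise_filter(a, b, config)
    lfc = log_fold_change(a, b)
    p = np.full(gene_ids.size, np.nan)
    q = np.full(gene_ids.size, np.nan)
    if keep.any():
        t, p_kept = welch_t_test(a[keep], b[keep], config.zero_variance)
        p[keep] = p_kept
        q[keep] = estimate_fdr(p_kept, config.fdr_method)
    sig = keep & (q <= config.fdr_alpha) & (np.abs(lfc) >= config.lfc_min)
    direction = np.where(lfc > 0, 1, -1)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "lfc": lfc,
            "p": p,
            "q": q,
            "noise_pass": keep,
            "significant": sig,
            "direction": direction,
        }
    )


def _list_from_table(table: pd.DataFrame, provenance) -> DEGList:
    hit = table[table["significant"]]
    return DEGList(
        dict(zip(hit["gene_id"], (int(d) for d in hit["direction"]))),
        tuple(provenance),
    )


def find_degs_between(group1: tuple[ExpressionMatrix, str],
                      group2: tuple[ExpressionMatrix, str],
                      config: DEGConfig = DEGConfig()) -> DEGList:
    """DEGs between condition groups that may live in two different matrices.

    Each argument is a ``(matrix, condition)`` pair; the two matrices must be
    row-aligned on the same gene ids (e.g. after ortholog pairing).  The LFC
    sign convention is first group minus second group.
    """
    (X, c1), (Y, c2) = group1, group2
    if not X.gene_ids.equals(Y.gene_ids):
        raise ValueError("matrices are not row-aligned on the same gene ids")
    ids1 = X.condition_samples(c1)
    ids2 = Y.condition_samples(c2)
    for cond, ids, M in ((c1, ids1, X), (c2, ids2, Y)):
        if len(ids) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
    a = X.values[ids1].to_numpy()
    b = Y.values[ids2].to_numpy()
    table = deg_table(a, b, X.gene_ids.to_numpy(), config)
    return _list_from_table(table, (c1, c2))


def find_degs(X: ExpressionMatrix, design: GroupDesign,
              config: DEGConfig = DEGConfig()) -> DEGList:
    """DEGs between C1 and C2 within one matrix (condition list)."""
    return find_degs_between(
        (X, design.condition_c1), (X, design.condition_c2), config
    )
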