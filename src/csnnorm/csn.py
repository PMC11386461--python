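"""CSN: cross-study, cross-species normalization by direct loss optimization.

The displacement model has three stages applied to an ortholog-aligned pair
(X, Y) of log2 matrices:

1. *Gene clustering.*  The row-concatenated gene vectors of X and Y are
   clustered with fuzzy c-means into k clusters (default 50); each gene is
   hard-assigned to its maximal-membership cluster.
2. *Weighted standardization.*  Target gene-wise moments are convex blends
   of the two datasets' own moments,

       mu_x_st = (w_xx mu_x + w_yx mu_y) / (w_xx + w_yx)   (same for sigma
       and symmetrically for Y),

   and each entry is re-standardized: x -> ((x - mu_x)/sigma_x) sigma_x_st
   + mu_x_st.
3. *Per-cluster affine displacement.*  Every entry of cluster i gets
   x -> x * alpha_i + beta_i, separately for X and Y.

This gives 4k + 4 free parameters (2k + 2 per dataset).  They are found by
CMA-ES minimizing

    F = -CSC - IOU(X) - IOU(Y)
        + m * (max(t - IOU(X), 0)^2 + max(t - IOU(Y), 0)^2),

where CSC and the IOUs are recomputed on the displaced pair each evaluation;
t is the minimal tolerated IOU and m the penalty weight.  The search starts
at the identity transform (alpha = 1, beta = 0, w_xx = w_yy = 1,
w_yx = w_xy = 0) and explores offsets within [-2, 2] around those centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._cmaes import cma_es_minimize, default_population_size
from ._fcm import fuzzy_c_means
from .data_model import ExpressionMatrix, GroupDesign
from .deg import DEGConfig
from .evaluation import (
    DEGListScheme,
    EvaluationReport,
    build_list_scheme,
    evaluate_pair,
)

__all__ = [
    "GeneClustering",
    "StandardizationWeights",
    "StandardizationMoments",
    "DisplacementParams",
    "LossConfig",
    "OptimizerConfig",
    "CSNResult",
    "cluster_genes",
    "standardize",
    "displace",
    "loss",
    "optimize",
    "csn_normalize",
]

_SIGMA_FLOOR = 1e-8
_WEIGHT_SUM_MIN = 1e-3


@dataclass
class GeneClustering:
    """Fuzzy c-means result with hard assignments (argmax membership)."""

    k: int
    membership: np.ndarray  # genes x k, rows sum to 1
    assignment: np.ndarray  # gene -> cluster index in 0..k-1
    fuzziness_exponent: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        sums = self.membership.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if self.assignment.shape[0] != self.membership.shape[0]:
            raise ValueError("assignment/membership length mismatch")


@dataclass(frozen=True)
class StandardizationWeights:
    """The four blending weights of the standardization stage.

    ``w_ij`` is the weight of dataset i's moments in dataset j's target
    moments; the pair sums (w_xx + w_yx, w_yy + w_xy) must stay >= 1e-3.
    """

    w_xx: float = 1.0
    w_yx: float = 0.0
    w_yy: float = 1.0
    w_xy: float = 0.0

    def validate(self) -> None:
        if min(self.w_xx, self.w_yx, self.w_yy, self.w_xy) < 0:
            raise ValueError("standardization weights must be nonnegative")
        if (self.w_xx + self.w_yx < _WEIGHT_SUM_MIN
                or self.w_yy + self.w_xy < _WEIGHT_SUM_MIN):
            raise ValueError(
                f"weight pair sums must be >= {_WEIGHT_SUM_MIN}"
            )


@dataclass
class StandardizationMoments:
    """Gene-wise input moments and the blended target moments."""

    mu_x: np.ndarray
    sigma_x: np.ndarray
    mu_y: np.ndarray
    sigma_y: np.ndarray
    mu_x_st: np.ndarray
    sigma_x_st: np.ndarray
    mu_y_st: np.ndarray
    sigma_y_st: np.ndarray


@dataclass
class DisplacementParams:
    """Per-cluster slopes/intercepts for both datasets plus the weights.

    Flattened layout (length 4k + 4):
    ``[alpha_x (k), beta_x (k), alpha_y (k), beta_y (k),
    w_xx, w_yx, w_yy, w_xy]``.
    """

    alpha_x: np.ndarray
    beta_x: np.ndarray
    alpha_y: np.ndarray
    beta_y: np.ndarray
    weights: StandardizationWeights

    @property
    def k(self) -> int:
        return self.alpha_x.size

    def encode(self) -> np.ndarray:
        w = self.weights
        return np.concatenate([
            self.alpha_x, self.beta_x, self.alpha_y, self.beta_y,
            [w.w_xx, w.w_yx, w.w_yy, w.w_xy],
        ])

    @classmethod
    def decode(cls, flat: np.ndarray, k: int) -> "DisplacementParams":
        flat = np.asarray(flat, dtype=float)
        if flat.size != 4 * k + 4:
            raise ValueError(f"expected length {4 * k + 4}, got {flat.size}")
        return cls(
            alpha_x=flat[0:k].copy(),
            beta_x=flat[k:2 * k].copy(),
            alpha_y=flat[2 * k:3 * k].copy(),
            beta_y=flat[3 * k:4 * k].copy(),
            weights=StandardizationWeights(*flat[4 * k:]),
        )

    @classmethod
    def identity(cls, k: int) -> "DisplacementParams":
        return cls(
            alpha_x=np.ones(k), beta_x=np.zeros(k),
            alpha_y=np.ones(k), beta_y=np.zeros(k),
            weights=StandardizationWeights(),
        )

    @classmethod
    def centers(cls, k: int) -> np.ndarray:
        """The flat vector around which the optimizer searches (identity)."""
        return cls.identity(k).encode()

    @classmethod
    def from_offsets(cls, offsets: np.ndarray, k: int) -> "DisplacementParams":
        """Centers + offsets, with weights made admissible.

        Weights are clipped to >= 0; if a pair sum falls below the guard,
        the dataset's own weight is raised to restore it (deterministic).
        """
        flat = cls.centers(k) + np.asarray(offsets, dtype=float)
        w = np.maximum(flat[4 * k:], 0.0)
        if w[0] + w[1] < _WEIGHT_SUM_MIN:
            w[0] = _WEIGHT_SUM_MIN - w[1]
        if w[2] + w[3] < _WEIGHT_SUM_MIN:
            w[2] = _WEIGHT_SUM_MIN - w[3]
        flat[4 * k:] = w
        return cls.decode(flat, k)


@dataclass(frozen=True)
class LossConfig:
    """Loss settings: IOU threshold t, penalty weight m, DEG thresholds.

    The default DEG configuration uses the variance floor so that degenerate
    rows produced mid-optimization do not abort the search.
    """

    t: float = 0.7
    m: float = 100.0
    deg_config: DEGConfig = field(
        default_factory=lambda: DEGConfig(zero_variance="floor")
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        if self.m <= 0:
            raise ValueError("m must be positive")


@dataclass(frozen=True)
class OptimizerConfig:
    """CMA-ES settings.

    The search variables are offsets from the identity centers, bounded in
    [var_min, var_max] = [-2, 2]; the initial step size is
    0.01 * (var_max - var_min) = 0.04; at most ``max_generations``
    generations are run with the standard population size
    4 + floor(3 ln N) unless overridden.
    """

    var_min: float = -2.0
    var_max: float = 2.0
    sigma0_factor: float = 0.01
    max_generations: int = 50
    population_size: int | None = None
    seed: int = 0

    @property
    def sigma0(self) -> float:
        return self.sigma0_factor * (self.var_max - self.var_min)

    def __post_init__(self) -> None:
        if self.var_max <= self.var_min:
            raise ValueError("var_max must exceed var_min")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class CSNResult:
    """Everything a CSN run produces."""

    x_new: ExpressionMatrix
    y_new: ExpressionMatrix
    best_params: DisplacementParams
    objective_history: list
    report: EvaluationReport
    initial_report: EvaluationReport
    best_loss: float
    initial_loss: float
    clustering: GeneClustering


# ---------------------------------------------------------------------------
# Displacement model
# ---------------------------------------------------------------------------

def cluster_genes(X: ExpressionMatrix, Y: ExpressionMatrix, k: int = 50,
                  seed: int = 0, fuzziness: float = 2.0) -> GeneClustering:
    """Fuzzy-cluster the merged gene vectors of a row-aligned pair.

    Each gene's feature vector is its values over all samples of X followed
    by all samples of Y.  Hard assignment is by maximal membership (ties go
    to the lowest cluster index).
    """
    if not X.gene_ids.equals(Y.gene_ids):
        raise ValueError("X and Y must be row-aligned on the same gene ids")
    merged = np.hstack([X.values.to_numpy(), Y.values.to_numpy()])
    if k > merged.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes {merged.shape[0]}")
    membership, _ = fuzzy_c_means(merged, k, m=fuzziness, seed=seed)
    assignment = membership.argmax(axis=1)  # argmax takes the lowest on ties
    return GeneClustering(
        k=k, membership=membership, assignment=assignment,
        fuzziness_exponent=fuzziness, seed=seed,
    )


def _moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = values.mean(axis=1)
    sigma = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros_like(mu)
    return mu, sigma


def _blend(wa: float, wb: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (wa * a + wb * b) / (wa + wb)


def _standardize_values(xv: np.ndarray, yv: np.ndarray,
                        weights: StandardizationWeights):
    weights.validate()
    mu_x, sigma_x = _moments(xv)
    mu_y, sigma_y = _moments(yv)
    w = weights
    mu_x_st = _blend(w.w_xx, w.w_yx, mu_x, mu_y)
    sigma_x_st = _blend(w.w_xx, w.w_yx, sigma_x, sigma_y)
    mu_y_st = _blend(w.w_yy, w.w_xy, mu_y, mu_x)
    sigma_y_st = _blend(w.w_yy, w.w_xy, sigma_y, sigma_x)
    moments = StandardizationMoments(
        mu_x, sigma_x, mu_y, sigma_y,
        mu_x_st, sigma_x_st, mu_y_st, sigma_y_st,
    )

    def transform(v, mu, sigma, mu_st, sigma_st):
        if np.array_equal(mu_st, mu) and np.array_equal(sigma_st, sigma):
            # identity weights: skip the arithmetic so inputs pass through
            # bit-for-bit instead of accumulating float round-off
            return v.copy()
        safe = np.maximum(sigma, _SIGMA_FLOOR)
        return ((v - mu[:, None]) / safe[:, None]) * sigma_st[:, None] + mu_st[:, None]

    return (
        transform(xv, mu_x, sigma_x, mu_x_st, sigma_x_st),
        transform(yv, mu_y, sigma_y, mu_y_st, sigma_y_st),
        moments,
    )


def standardize(X: ExpressionMatrix, Y: ExpressionMatrix,
                weights: StandardizationWeights):
    """Re-standardize both datasets toward blended gene-wise moments.

    Constant genes (sigma below 1e-8) are shifted to the blended mean only.
    Returns ``(X_st, Y_st, moments)``.
    """
    xv, yv, moments = _standardize_values(
        X.values.to_numpy(), Y.values.to_numpy(), weights
    )
    return X.with_values(xv), Y.with_values(yv), moments


def _displace_values(x_st: np.ndarray, y_st: np.ndarray,
                     assignment: np.ndarray, params: DisplacementParams):
    ax = params.alpha_x[assignment][:, None]
    bx = params.beta_x[assignment][:, None]
    ay = params.alpha_y[assignment][:, None]
    by = params.beta_y[assignment][:, None]
    return x_st * ax + bx, y_st * ay + by


def displace(X_st: ExpressionMatrix, Y_st: ExpressionMatrix,
             clustering: GeneClustering, params: DisplacementParams):
    """Apply each cluster's affine map to its genes, per dataset."""
    if clustering.assignment.shape[0] != X_st.shape[0]:
        raise ValueError("clustering does not cover all genes")
    if params.k != clustering.k:
        raise ValueError("params length does not match the cluster count")
    xv, yv = _displace_values(
        X_st.values.to_numpy(), Y_st.values.to_numpy(),
        clustering.assignment, params,
    )
    return X_st.with_values(xv), Y_st.with_values(yv)


def apply_displacement(X: ExpressionMatrix, Y: ExpressionMatrix,
                       clustering: GeneClustering,
                       params: DisplacementParams):
    """standardize then displace: the full CSN transform."""
    X_st, Y_st, _ = standardize(X, Y, params.weights)
    return displace(X_st, Y_st, clustering, params)


# ---------------------------------------------------------------------------
# Loss and optimization
# ---------------------------------------------------------------------------

def _loss_from_report(report: EvaluationReport, config: LossConfig) -> float:
    iou_x, iou_y = report.iou_x, report.iou_y
    penalty = config.m * (
        max(config.t - iou_x, 0.0) ** 2 + max(config.t - iou_y, 0.0) ** 2
    )
    return -report.csc - iou_x - iou_y + penalty


def loss(X: ExpressionMatrix, Y: ExpressionMatrix,
         params: DisplacementParams, clustering: GeneClustering,
         baseline_condition_lists: tuple, design: GroupDesign,
         config: LossConfig) -> float:
    """Objective value of one candidate transformation.

    Applies the transform, recomputes the six-list scheme on the displaced
    pair, and combines CSC with the two IOUs against the pre-normalization
    condition lists.
    """
    x_new, y_new = apply_displacement(X, Y, clustering, params)
    scheme = build_list_scheme(x_new, y_new, design, config.deg_config)
    report = evaluate_pair(scheme, baseline_condition_lists)
    return _loss_from_report(report, config)


def optimize(X: ExpressionMatrix, Y: ExpressionMatrix, design: GroupDesign,
             clustering: GeneClustering,
             loss_config: LossConfig = LossConfig(),
             opt_config: OptimizerConfig = OptimizerConfig()) -> CSNResult:
    """CMA-ES search over the 4k+4 displacement parameters.

    The search runs in offset space around the identity centers, clipped to
    [var_min, var_max]; the identity point is evaluated first so the
    returned best is never worse than doing nothing.
    """
    k = clustering.k
    n_params = 4 * k + 4
    xv = X.values.to_numpy()
    yv = Y.values.to_numpy()
    gene_ids = X.gene_ids.to_numpy()

    base_scheme = build_list_scheme(X, Y, design, loss_config.deg_config)
    baseline_lists = base_scheme.condition_lists
    initial_report = evaluate_pair(base_scheme, baseline_lists)

    # hot loop works on raw arrays; DEG lists via the shared evaluation path
    from .deg import deg_table, DEGList  # local alias for clarity

    c1, c2 = design.condition_c1, design.condition_c2
    cond = X.samples["condition"]
    x_c1 = np.flatnonzero((cond == c1).to_numpy())
    x_c2 = np.flatnonzero((cond == c2).to_numpy())
    cond_y = Y.samples["condition"]
    y_c1 = np.flatnonzero((cond_y == c1).to_numpy())
    y_c2 = np.flatnonzero((cond_y == c2).to_numpy())

    def scheme_from_arrays(xn: np.ndarray, yn: np.ndarray) -> DEGListScheme:
        groups = (
            (xn[:, x_c1], xn[:, x_c2], (c1, c2)),
            (yn[:, y_c1], yn[:, y_c2], (c1, c2)),
            (xn[:, x_c1], yn[:, y_c2], (c1, c2)),
            (xn[:, x_c2], yn[:, y_c1], (c2, c1)),
            (xn[:, x_c1], yn[:, y_c1], (c1, c1)),
            (xn[:, x_c2], yn[:, y_c2], (c2, c2)),
        )
        lists = []
        for a, b, prov in groups:
            table = deg_table(a, b, gene_ids, loss_config.deg_config)
            hit = table[table["significant"]]
            lists.append(DEGList(
                dict(zip(hit["gene_id"], (int(d) for d in hit["direction"]))),
                prov,
            ))
        return DEGListScheme(tuple(lists))

    cache: dict[bytes, float] = {}

    def objective(offsets: np.ndarray) -> float:
        key = offsets.tobytes()
        if key in cache:
            return cache[key]
        params = DisplacementParams.from_offsets(offsets, k)
        x_st, y_st, _ = _standardize_values(xv, yv, params.weights)
        xn, yn = _displace_values(x_st, y_st, clustering.assignment, params)
        scheme = scheme_from_arrays(xn, yn)
        report = evaluate_pair(scheme, baseline_lists)
        value = _loss_from_report(report, loss_config)
        cache[key] = value
        return value

    result = cma_es_minimize(
        objective,
        x0=np.zeros(n_params),
        sigma0=opt_config.sigma0,
        bounds=(opt_config.var_min, opt_config.var_max),
        max_generations=opt_config.max_generations,
        popsize=opt_config.population_size,
        seed=opt_config.seed,
    )

    best_params = DisplacementParams.from_offsets(result.best_x, k)
    x_new, y_new = apply_displacement(X, Y, clustering, best_params)
    final_scheme = build_list_scheme(x_new, y_new, design, loss_config.deg_config)
    final_report = evaluate_pair(final_scheme, baseline_lists)

    initial_loss = _loss_from_report(initial_report, loss_config)
    history = [initial_loss] + result.history
    return CSNResult(
        x_new=x_new,
        y_new=y_new,
        best_params=best_params,
        objective_history=history,
        report=final_report,
        initial_report=initial_report,
        best_loss=result.best_f,
        initial_loss=initial_loss,
        clustering=clustering,
    )


def csn_normalize(X: ExpressionMatrix, Y: ExpressionMatrix,
                  design: GroupDesign, k: int = 50,
                  loss_config: LossConfig = LossConfig(),
                  opt_config: OptimizerConfig = OptimizerConfig(),
                  fuzziness: float = 2.0) -> CSNResult:
    """Convenience composition: cluster genes, then optimize the transform."""
    clustering = cluster_genes(X, Y, k=k, seed=opt_config.seed,
                               fuzziness=fuzziness)
    return optimize(X, Y, design, clustering, loss_config, opt_config)
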