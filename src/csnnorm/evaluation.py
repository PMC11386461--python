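"""Performance evaluation of a cross-study normalization via DEG overlaps.

Given two datasets H and M (e.g. a human and a mouse study) sharing two
conditions C1 and C2, six DEG lists are formed:

    1  H_C1 - H_C2   condition list (biological contrast within H)
    2  M_C1 - M_C2   condition list (within M)
    3  H_C1 - M_C2   cross list
    4  H_C2 - M_C1   cross list
    5  H_C1 - M_C1   species list (same condition, different dataset)
    6  H_C2 - M_C2   species list

A good normalization makes the cross lists resemble the condition lists
(high CCA), keeps the species lists small and separate (low SA), and leaves
each dataset's own condition list untouched (IOU near 1).  CSC = CCA / SA
combines the first two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix, GroupDesign
from .deg import DEGConfig, DEGList, find_degs_between

__all__ = [
    "LIST_NAMES",
    "DEGListScheme",
    "EvaluationReport",
    "build_list_scheme",
    "proportion",
    "cca",
    "cca_terms",
    "sa",
    "sa_terms",
    "csc",
    "iou",
    "intersection_matrix",
    "split_by_direction",
    "evaluate_pair",
]

LIST_NAMES = (
    "H_C1-H_C2",
    "M_C1-M_C2",
    "H_C1-M_C2",
    "H_C2-M_C1",
    "H_C1-M_C1",
    "H_C2-M_C2",
)

#: condition/cross list positions (0-based) and species list positions
_CC = (0, 1, 2, 3)
_SP = (4, 5)

CSC_EPSILON = 1e-6


@dataclass(frozen=True)
class DEGListScheme:
    """The six DEG lists in fixed positional order (see module docstring)."""

    lists: tuple

    def __post_init__(self) -> None:
        if len(self.lists) != 6:
            raise ValueError("a list scheme holds exactly six DEG lists")

    def __getitem__(self, i: int) -> DEGList:
        return self.lists[i]

    @property
    def condition_lists(self) -> tuple:
        return self.lists[0], self.lists[1]


@dataclass
class EvaluationReport:
    """All evaluation indices for one (possibly normalized) dataset pair."""

    cca: float
    sa: float
    csc: float
    iou_x: float | None
    iou_y: float | None
    proportions: dict
    intersection_matrix: np.ndarray
    direction_split_matrix: np.ndarray
    list_sizes: tuple

    def to_dict(self) -> dict:
        return {
            "cca": self.cca,
            "sa": self.sa,
            "csc": self.csc,
            "iou_x": self.iou_x,
            "iou_y": self.iou_y,
            "list_sizes": dict(zip(LIST_NAMES, self.list_sizes)),
            "intersection_matrix": self.intersection_matrix.tolist(),
            "direction_split_matrix": self.direction_split_matrix.tolist(),
        }


def build_list_scheme(X: ExpressionMatrix, Y: ExpressionMatrix,
                      design: GroupDesign,
                      config: DEGConfig = DEGConfig()) -> DEGListScheme:
    """Compute the six DEG lists for an ortholog-aligned dataset pair.

    ``X`` plays the H role, ``Y`` the M role.  Both must contain >= 2
    samples of each condition.
    """
    c1, c2 = design.condition_c1, design.condition_c2
    for name, M in (("X", X), ("Y", Y)):
        for cond in (c1, c2):
            if len(M.condition_samples(cond)) < 2:
                raise ValueError(
                    f"dataset {name} has fewer than 2 samples of "
                    f"condition {cond!r}"
                )
    pairs = (
        ((X, c1), (X, c2)),
        ((Y, c1), (Y, c2)),
        ((X, c1), (Y, c2)),
        ((X, c2), (Y, c1)),
        ((X, c1), (Y, c1)),
        ((X, c2), (Y, c2)),
    )
    return DEGListScheme(
        tuple(find_degs_between(g1, g2, config) for g1, g2 in pairs)
    )


def proportion(list_i: DEGList, list_j: DEGList) -> float:
    """P_ij/i: fraction of list i's genes that also appear in list j.

    An empty list i yields 0 (no overlap evidence).
    """
    if list_i.size == 0:
        return 0.0
    return len(list_i.genes & list_j.genes) / list_i.size


def cca_terms(scheme: DEGListScheme) -> dict:
    """The 12 ordered-pair proportions over the condition and cross lists."""
    return {
        (i + 1, j + 1): proportion(scheme[i], scheme[j])
        for i in _CC
        for j in _CC
        if i != j
    }


def cca(scheme: DEGListScheme) -> float:
    """Cross-Condition Average: mean of the 12 condition/cross proportions."""
    terms = cca_terms(scheme)
    return sum(terms.values()) / len(terms)


def sa_terms(scheme: DEGListScheme) -> dict:
    """The 16 proportions pairing each species list with lists 1-4.

    For each unordered intersection (i, j), i in 1..4, j in 5..6, both
    P_ij/i and P_ij/j enter (keyed (i, j) and (j, i) respectively).
    """
    terms = {}
    for i in _CC:
        for j in _SP:
            terms[(i + 1, j + 1)] = proportion(scheme[i], scheme[j])
            terms[(j + 1, i + 1)] = proportion(scheme[j], scheme[i])
    return terms


def sa(scheme: DEGListScheme) -> float:
    """Species Average: the 16 species-list proportions divided by 16."""
    return sum(sa_terms(scheme).values()) / 16.0


def csc(scheme: DEGListScheme) -> float:
    """Cross-Study Comparison index: CCA / SA (higher = better).

    SA = 0 is guarded by an epsilon floor of 1e-6 with a warning; CCA = 0
    gives 0 regardless.
    """
    num = cca(scheme)
    den = sa(scheme)
    if num == 0.0:
        return 0.0
    if den < CSC_EPSILON:
        warnings.warn(
            "SA is 0; CSC uses the 1e-6 denominator floor", RuntimeWarning,
            stacklevel=2,
        )
        den = CSC_EPSILON
    return num / den


def iou(list_before: DEGList, list_after: DEGList) -> float:
    """Intersection-over-union of a condition list before vs after.

    Two empty lists give 1 (the normalization changed nothing).
    """
    a, b = list_before.genes, list_after.genes
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def intersection_matrix(scheme: DEGListScheme) -> np.ndarray:
    """6x6 pairwise intersection counts; diagonal = list sizes."""
    mat = np.zeros((6, 6), dtype=int)
    sets = [l.genes for l in scheme.lists]
    for i in range(6):
        for j in range(6):
            mat[i, j] = len(sets[i] & sets[j])
    return mat


def split_by_direction(scheme: DEGListScheme) -> np.ndarray:
    """12x12 intersection counts after splitting each list by direction.

    Row/column order: list 1 up (">"), list 1 down ("<"), list 2 up, ... —
    "up" meaning higher expression in the first-named group.
    """
    subs = []
    for lst in scheme.lists:
        subs.append(lst.subset(+1))
        subs.append(lst.subset(-1))
    mat = np.zeros((12, 12), dtype=int)
    for i in range(12):
        for j in range(12):
            mat[i, j] = len(subs[i] & subs[j])
    return mat


def evaluate_pair(scheme: DEGListScheme,
                  baseline_condition_lists: tuple | None = None
                  ) -> EvaluationReport:
    """Assemble the full report for a scheme.

    ``baseline_condition_lists`` are the two pre-normalization condition
    lists (X's then Y's); when given, IOU of each dataset is computed
    against the scheme's own condition lists.
    """
    iou_x = iou_y = None
    if baseline_condition_lists is not None:
        base_x, base_y = baseline_condition_lists
        iou_x = iou(base_x, scheme[0])
        iou_y = iou(base_y, scheme[1])
    props = cca_terms(scheme)
    props.update(sa_terms(scheme))
    return EvaluationReport(
        cca=cca(scheme),
        sa=sa(scheme),
        csc=csc(scheme),
        iou_x=iou_x,
        iou_y=iou_y,
        proportions=props,
        intersection_matrix=intersection_matrix(scheme),
        direction_split_matrix=split_by_direction(scheme),
        list_sizes=tuple(l.size for l in scheme.lists),
    )
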