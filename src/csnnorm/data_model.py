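"""Core containers and the preprocessing chain for cross-study expression data.

The unit of data is a gene x sample matrix of bulk RNA-seq expression values
together with per-sample metadata (study, species, condition).  Before any
cross-study work, raw read counts are library-size normalized to counts per
million, zeros are replaced by 1 and values are log2-transformed; two
datasets are then restricted to their common genes (same species) or to
one-to-one ortholog pairs (different species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GroupDesign",
    "OrthologMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ortholog_map",
    "library_size_normalize",
    "log2_transform",
    "restrict_to_common_genes",
    "pair_by_orthologs",
]

_META_COLUMNS = ("study", "species", "condition")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  Units are
        raw read counts before preprocessing and log2(normalized counts)
        after :func:`log2_transform`.
    samples
        DataFrame indexed by sample id with columns ``study``, ``species``
        and ``condition``, aligned with ``values.columns``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.values.index
        cols = self.values.columns
        for name, idx in (("gene", genes), ("sample", cols)):
            if idx.has_duplicates:
                dup = idx[idx.duplicated()][0]
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if len(self.samples) != len(cols) or not self.samples.index.equals(cols):
            missing = cols.difference(self.samples.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from metadata: {list(missing[:5])}"
                )
            self.samples = self.samples.loc[cols]
        for col in _META_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy())

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        """Sub-matrix restricted to ``sample_ids`` (order preserved)."""
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.sample_ids)
        if len(missing):
            raise KeyError(f"unknown sample ids: {list(missing[:5])}")
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def condition_samples(self, condition: str) -> pd.Index:
        """Ids of samples annotated with ``condition``."""
        mask = self.samples["condition"] == condition
        return self.samples.index[mask]

    def with_values(self, array: np.ndarray) -> "ExpressionMatrix":
        """Same ids/metadata, new value array (shape must match)."""
        if array.shape != self.values.shape:
            raise ValueError("value array shape mismatch")
        return ExpressionMatrix(
            pd.DataFrame(array, index=self.gene_ids, columns=self.sample_ids),
            self.samples.copy(),
        )


@dataclass(frozen=True)
class GroupDesign:
    """Pair of condition labels under comparison (C1 vs C2)."""

    condition_c1: str
    condition_c2: str

    def group_sample_ids(self, X: ExpressionMatrix) -> tuple[pd.Index, pd.Index]:
        """Sample ids of C1 and C2 within ``X``; each group needs >= 2."""
        out = []
        for cond in (self.condition_c1, self.condition_c2):
            ids = X.condition_samples(cond)
            if len(ids) < 2:
                raise ValueError(
                    f"condition {cond!r} has {len(ids)} samples (< 2) in dataset"
                )
            out.append(ids)
        return out[0], out[1]


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one ortholog pairs between two gene id namespaces."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for side, name in ((0, "first"), (1, "second")):
            seen: set[str] = set()
            for pair in self.pairs:
                gid = pair[side]
                if gid in seen:
                    raise ValueError(
                        f"ortholog map is not one-to-one: {gid!r} appears "
                        f"more than once on the {name} side"
                    )
                seen.add(gid)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# I/O — tab-separated, UTF-8, genes as rows
# ---------------------------------------------------------------------------

def read_expression_matrix(path, metadata_path=None) -> ExpressionMatrix:
    """Read an expression TSV (first column ``gene_id``) plus metadata TSV.

    The metadata file has one row per sample with columns ``sample_id``,
    ``study``, ``species`` and ``condition``.  When ``metadata_path`` is
    omitted, metadata columns are filled with empty strings (useful for
    operations that ignore sample annotation, e.g. the rank baseline).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    if metadata_path is None:
        samples = pd.DataFrame(
            {c: [""] * values.shape[1] for c in _META_COLUMNS},
            index=values.columns,
        )
    else:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "sample_id" not in meta.columns:
            raise ValueError(f"{metadata_path} lacks a 'sample_id' column")
        if meta["sample_id"].duplicated().any():
            dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        samples = meta.set_index("sample_id")
        missing = values.columns.difference(samples.index)
        if len(missing):
            raise ValueError(
                f"samples missing from metadata {metadata_path}: "
                f"{list(missing[:5])}"
            )
        samples = samples.loc[values.columns]
    return ExpressionMatrix(values, samples)


def write_expression_matrix(X: ExpressionMatrix, path, metadata_path=None) -> None:
    """Write the expression TSV (and optionally the metadata TSV)."""
    out = X.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if metadata_path is not None:
        meta = X.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV of one-to-one ortholog pairs."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] < 2:
        raise ValueError(f"{path} must have two columns of gene ids")
    a, b = tab.columns[:2]
    return OrthologMap(tuple(zip(tab[a], tab[b])))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def library_size_normalize(X: ExpressionMatrix, scale: float = 1e6) -> ExpressionMatrix:
    """Scale each sample's counts so the column sums to ``scale`` (CPM).

    Raises on negative counts or an all-zero sample.
    """
    vals = X.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("raw counts must be nonnegative")
    totals = vals.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {X.sample_ids[zero[0]]!r} has total count 0"
        )
    return X.with_values(vals * (scale / totals))


def log2_transform(X: ExpressionMatrix, floor_at_one: bool = False) -> ExpressionMatrix:
    """Replace zeros by 1, then take elementwise log2.

    Values in (0, 1) are left as-is by default and therefore map to small
    negative log2 values; ``floor_at_one=True`` clamps them to 1 first.
    """
    vals = X.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("log2_transform requires nonnegative values")
    vals = vals.copy()
    if floor_at_one:
        vals[vals < 1] = 1.0
    else:
        vals[vals == 0] = 1.0
    return X.with_values(np.log2(vals))


def preprocess_counts(X: ExpressionMatrix, scale: float = 1e6,
                      floor_at_one: bool = False) -> ExpressionMatrix:
    """CPM then log2: the full raw-count preprocessing chain."""
    return log2_transform(library_size_normalize(X, scale), floor_at_one)


def restrict_to_common_genes(
    X: ExpressionMatrix, Y: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two same-species matrices to their shared gene ids.

    Both outputs carry exactly the intersection, in X's gene order.
    """
    common = X.gene_ids.intersection(Y.gene_ids, sort=False)
    # keep X's row order
    common = X.gene_ids[X.gene_ids.isin(common)]
    if len(common) == 0:
        raise ValueError("no genes shared between the two matrices")
    return (
        ExpressionMatrix(X.values.loc[common], X.samples),
        ExpressionMatrix(Y.values.loc[common], Y.samples),
    )


def pair_by_orthologs(
    X: ExpressionMatrix, Y: ExpressionMatrix, orthologs: OrthologMap
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Align two cross-species matrices on one-to-one ortholog pairs.

    Pairs whose genes are absent from either matrix are dropped.  Both
    outputs are re-indexed by the shared synthetic key ``"<a>|<b>"`` so that
    downstream set operations act on a single namespace.
    """
    x_genes = set(X.gene_ids)
    y_genes = set(Y.gene_ids)
    a_ids, b_ids, keys = [], [], []
    for a, b in orthologs.pairs:
        key = f"{a}|{b}"
        if a in x_genes and b in y_genes:
            a_ids.append(a)
            b_ids.append(b)
            keys.append(key)
        elif key in x_genes and key in y_genes:  # already paired: idempotent
            a_ids.append(key)
            b_ids.append(key)
            keys.append(key)
    if not keys:
        raise ValueError("no ortholog pair is present in both matrices")
    xv = X.values.loc[a_ids].copy()
    yv = Y.values.loc[b_ids].copy()
    xv.index = pd.Index(keys, name=X.values.index.name)
    yv.index = pd.Index(keys, name=Y.values.index.name)
    return ExpressionMatrix(xv, X.samples), ExpressionMatrix(yv, Y.samples)
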