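"""Estimating pair-score weights and the reference tree from expression.

When no external knowledge of the cell-type hierarchy is available, the
weights can be derived from the same labelled expression matrix the
clustering was run on: per-type mean log-expression profiles are
computed, the genes most variable across those type means are kept, and

* ``W1`` off-diagonals become the Pearson correlation between two
  types' mean profiles (similar types earn more partial credit when
  merged), clamped below at 0;
* ``W0`` diagonals become one minus the mean pairwise correlation among
  a type's cells (heterogeneous types are cheaper to split);
* the reference dendrogram is agglomerative clustering of the type mean
  profiles, with node heights standardized by the maximum.

Expression values are transformed as log(x + 1) before any means,
variances or correlations; the log base is irrelevant because gene
ranking and Pearson correlation are invariant to affine rescaling.
Batch correction, normalization and imputation are out of scope: pass a
matrix that is already on a comparable scale across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .errors import DegenerateMetricError, SchemaError
from .partitions import PartitionLabels
from .structured_entropy import ReferenceTree
from .weighted_rand import WeightMatrices

__all__ = [
    "ExpressionMatrix",
    "MeanProfiles",
    "mean_profiles",
    "top_variable_genes",
    "estimate_w1",
    "estimate_w0",
    "build_reference_tree",
    "estimate_weights",
    "weights_from_tree",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cells matrix of non-negative expression values."""

    values: np.ndarray
    gene_ids: tuple
    cell_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if values.ndim != 2:
            raise SchemaError("expression values must be a 2-d matrix")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise SchemaError(
                f"expression shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.isfinite(values).all():
            raise SchemaError("expression contains non-finite values")
        if values.min() < 0:
            raise SchemaError("expression values must be non-negative")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise SchemaError(f"duplicate {name} ids in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class MeanProfiles:
    """Types x genes matrix of per-type mean log(x+1) expression."""

    values: np.ndarray
    type_labels: tuple
    gene_ids: tuple
    cell_counts: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        counts = np.asarray(self.cell_counts, dtype=np.int64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_counts", counts)
        object.__setattr__(
            self, "type_labels", tuple(str(t) for t in self.type_labels)
        )
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if values.shape != (len(self.type_labels), len(self.gene_ids)):
            raise SchemaError("mean-profile shape does not match labels")
        if counts.shape != (len(self.type_labels),) or (counts < 1).any():
            raise SchemaError("every type needs a positive cell count")


def _cells_of_type(expr: ExpressionMatrix, ref: PartitionLabels):
    """Column indices of each reference type's cells, in type order."""
    label = ref.label_by_id
    unlabelled = [c for c in expr.cell_ids if c not in label]
    if unlabelled:
        raise SchemaError(
            f"cells without a reference label: {unlabelled[:10]}"
        )
    cols: dict = {t: [] for t in ref.groups}
    for k, c in enumerate(expr.cell_ids):
        cols[label[c]].append(k)
    empty = [t for t, ix in cols.items() if not ix]
    if empty:
        raise SchemaError(f"reference types with zero cells in the matrix: {empty}")
    return cols


def mean_profiles(expr: ExpressionMatrix, ref: PartitionLabels) -> MeanProfiles:
    """Per-type mean of log(x+1)-transformed expression."""
    cols = _cells_of_type(expr, ref)
    log_values = np.log1p(expr.values)
    rows = np.stack([log_values[:, cols[t]].mean(axis=1) for t in ref.groups])
    counts = np.array([len(cols[t]) for t in ref.groups])
    return MeanProfiles(rows, ref.groups, expr.gene_ids, counts)


def top_variable_genes(mp: MeanProfiles, k: int = 1000) -> np.ndarray:
    """Indices of the k genes with the largest across-type variance of
    mean log expression (ascending index order; ties resolved by gene
    order)."""
    n_genes = len(mp.gene_ids)
    if n_genes < 2:
        raise SchemaError("need at least 2 genes to rank variability")
    if k < 2:
        raise SchemaError(f"k must be at least 2, got {k}")
    if k > n_genes:
        warnings.warn(
            f"requested top {k} genes but only {n_genes} available; using all"
        )
        k = n_genes
    var = mp.values.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:k])


def _corrcoef(rows: np.ndarray, context: str, names: Sequence) -> np.ndarray:
    sd = rows.std(axis=1)
    flat = [str(names[k]) for k in np.flatnonzero(sd == 0)]
    if flat:
        raise SchemaError(
            f"zero-variance profile over the selected genes for {context}: {flat}"
        )
    return np.corrcoef(rows)


def estimate_w1(mp: MeanProfiles, genes: np.ndarray) -> np.ndarray:
    """W1: unit diagonal, off-diagonal = Pearson correlation of the two
    types' mean profiles over the selected genes, clamped below at 0."""
    if len(mp.type_labels) < 2:
        raise SchemaError("need at least 2 types to estimate W1")
    rows = mp.values[:, np.asarray(genes, dtype=int)]
    r = _corrcoef(rows, "type", mp.type_labels)
    w1 = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(w1, 1.0)
    return (w1 + w1.T) / 2.0


def estimate_w0(
    expr: ExpressionMatrix,
    ref: PartitionLabels,
    genes: np.ndarray,
    method: str = "pairwise",
) -> np.ndarray:
    """W0: unit off-diagonal; diagonal = within-type heterogeneity.

    ``method='pairwise'`` (default): 1 minus the mean pairwise Pearson
    correlation among the type's cells over the selected genes.
    ``method='to_mean'``: the mean of (1 - r) between each cell and the
    type's mean profile.  Either way the diagonal is clamped into
    [0, 1].  A single-cell type gets diagonal 0 (no heterogeneity is
    measurable, so splitting it carries the full penalty) with a
    warning.
    """
    if method not in ("pairwise", "to_mean"):
        raise ValueError(f"unknown heterogeneity method {method!r}")
    genes = np.asarray(genes, dtype=int)
    cols = _cells_of_type(expr, ref)
    log_values = np.log1p(expr.values[genes, :])
    j = len(ref.groups)
    w0 = np.ones((j, j))
    for k, t in enumerate(ref.groups):
        cells = log_values[:, cols[t]].T  # cells x genes
        if cells.shape[0] == 1:
            warnings.warn(
                f"type {t!r} has a single cell; setting its W0 diagonal to 0"
            )
            w0[k, k] = 0.0
            continue
        if method == "pairwise":
            r = _corrcoef(cells, f"cells of type {t!r}", cols[t])
            iu = np.triu_indices(cells.shape[0], 1)
            mean_r = float(r[iu].mean())
        else:
            centre = cells.mean(axis=0)
            if centre.std() == 0:
                raise SchemaError(
                    f"zero-variance mean profile for type {t!r} over the "
                    "selected genes"
                )
            r_each = _corrcoef(
                np.vstack([centre, cells]), f"cells of type {t!r}", ["mean"] + cols[t]
            )[0, 1:]
            mean_r = float(r_each.mean())
        w0[k, k] = float(np.clip(1.0 - mean_r, 0.0, 1.0))
    return w0


def build_reference_tree(
    mp: MeanProfiles,
    genes: np.ndarray,
    method: str = "complete",
    metric: str = "euclidean",
) -> ReferenceTree:
    """Agglomerative clustering of type mean profiles into a dendrogram.

    Heights are standardized by the maximum merge height, so the root
    sits at 1 and the step weights start at d_1 = 1.
    """
    if len(mp.type_labels) < 2:
        raise SchemaError("need at least 2 types to build a tree")
    rows = mp.values[:, np.asarray(genes, dtype=int)]
    dists = pdist(rows, metric=metric)
    if dists.max() == 0:
        raise DegenerateMetricError(
            "all type mean profiles are identical; the tree is degenerate"
        )
    z = _scipy_linkage(dists, method=method)
    heights = z[:, 2] / z[:, 2].max()
    if heights.min() <= 0:
        tied = [
            str(mp.type_labels[int(i)])
            for i in z[heights <= 0][:, :2].ravel()
            if i < len(mp.type_labels)
        ]
        raise DegenerateMetricError(
            f"types with identical mean profiles collapse to height 0: {tied}"
        )
    return ReferenceTree(
        leaf_names=mp.type_labels,
        children=z[:, :2].astype(np.int64),
        heights=heights,
    )


def estimate_weights(
    expr: ExpressionMatrix,
    ref: PartitionLabels,
    n_top_genes: int = 1000,
    heterogeneity: str = "pairwise",
) -> WeightMatrices:
    """One-call estimation of canonical W1/W0 from labelled expression."""
    mp = mean_profiles(expr, ref)
    genes = top_variable_genes(mp, k=n_top_genes)
    return WeightMatrices(
        w1=estimate_w1(mp, genes),
        w0=estimate_w0(expr, ref, genes, method=heterogeneity),
        type_labels=ref.groups,
    )


def weights_from_tree(
    tree: ReferenceTree,
    w0_diag: float | Sequence = 0.0,
    type_labels: Optional[Sequence] = None,
) -> WeightMatrices:
    """Canonical weights read off a reference tree.

    W1[j, j'] = 1 - (MRCA height / root height): types merging low on
    the tree are similar and earn high partial credit.  W0 has unit
    off-diagonal and a user-chosen diagonal (default 0, the classical
    full penalty for splitting a type), since within-type heterogeneity
    is not encoded in the tree.
    """
    h = tree.mrca_heights()
    w1 = 1.0 - h / h.max()
    np.fill_diagonal(w1, 1.0)
    j = tree.n_leaves
    w0 = np.ones((j, j))
    np.fill_diagonal(w0, np.broadcast_to(np.asarray(w0_diag, dtype=float), (j,)))
    wm = WeightMatrices(w1=w1, w0=w0, type_labels=tree.leaf_names)
    if type_labels is not None:
        order = [tree.leaf_names.index(str(t)) for t in type_labels]
        wm = WeightMatrices(
            w1=wm.w1[np.ix_(order, order)],
            w0=wm.w0[np.ix_(order, order)],
            type_labels=tuple(type_labels),
        )
    return wm
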