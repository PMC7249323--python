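"""Rand-type agreement indices, classical and hierarchy-weighted.

The Rand index (RI) is the fraction of the C(n,2) cell pairs whose
same/different-group relationship agrees between a clustering C and a
reference R.  The weighted variant replaces the 0/1 pair score with
entries of two J x J matrices defined over the reference types: a pair
of cells of types (j, j') co-clustered by C scores ``W1[j, j']``, a pair
kept apart scores ``W0[j, j']``.  The weighted agreement score is

    S*(C, R) = sum over pairs of the per-pair score,

and the weighted Rand index is wRI = S*(C, R) / S*(R, R), where S*(R, R)
treats the reference itself as the clustering.  In canonical form W1 has
unit diagonal (recovering a true tie earns full credit; merging distinct
types earns the partial credit W1[j, j'] < 1, typically their expression
similarity) and W0 has unit off-diagonal (keeping distinct types apart
earns full credit; splitting type j costs 1 - W0[j, j], which can be
less than total for heterogeneous types).  With W1 = I and W0 = 1 - I
the score reduces exactly to the classical RI.

All scores here are computed from the contingency table in O(I J^2);
:func:`hiermetrics.partitions.pairwise_oracle` is the quadratic
reference implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateMetricError, SchemaError
from .partitions import (
    ContingencyTable,
    PairCounts,
    PartitionLabels,
    _n_pairs,
    build_contingency,
    pair_counts,
)

__all__ = [
    "WeightMatrices",
    "RandReport",
    "rand_index",
    "adjusted_rand_index",
    "weighted_agreement_score",
    "weighted_rand_index",
    "weighted_predictive_values",
    "rand_report",
]

_SYM_TOL = 1e-8


def _symmetrize(m: np.ndarray, name: str) -> np.ndarray:
    """Fill a matrix from its upper triangle.

    The lower triangle is ignored unless it is populated and disagrees
    with the upper triangle beyond ``1e-8``, which is an error.
    """
    m = np.asarray(m, dtype=float)
    upper = np.triu(m, 1)
    lower = np.tril(m, -1)
    if not np.allclose(lower, 0.0, atol=_SYM_TOL):
        if not np.allclose(lower.T, upper, atol=_SYM_TOL):
            raise SchemaError(
                f"{name} has inconsistent upper and lower triangles "
                f"(max deviation {np.abs(lower.T - upper).max():.3g})"
            )
    return np.diag(np.diag(m)) + upper + upper.T


@dataclass(frozen=True)
class WeightMatrices:
    """Pair-score matrices W1 (co-clustered) and W0 (separated).

    Both are symmetric J x J with entries in [0, 1], indexed by
    ``type_labels``.  Canonical form (the default, and the form the
    interpretation of wRI assumes) additionally requires diag(W1) = 1
    and off-diagonal W0 = 1; pass ``canonical=False`` to accept any
    valid symmetric matrices.
    """

    w1: np.ndarray
    w0: np.ndarray
    type_labels: tuple
    canonical: bool = True

    def __post_init__(self):
        labels = tuple(str(v) for v in self.type_labels)
        object.__setattr__(self, "type_labels", labels)
        if len(set(labels)) != len(labels):
            raise SchemaError("duplicate type labels in weight matrices")
        j = len(labels)
        mats = {}
        for name in ("w1", "w0"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (j, j):
                raise SchemaError(f"{name} must be {j}x{j}, got {m.shape}")
            if not np.isfinite(m).all():
                raise SchemaError(f"{name} contains non-finite entries")
            m = _symmetrize(m, name)
            if m.min() < -1e-12 or m.max() > 1 + 1e-12:
                raise SchemaError(f"{name} entries must lie in [0, 1]")
            mats[name] = np.clip(m, 0.0, 1.0)
            object.__setattr__(self, name, mats[name])
        if self.canonical:
            if not np.allclose(np.diag(mats["w1"]), 1.0, atol=1e-12):
                raise SchemaError(
                    "canonical W1 must have unit diagonal "
                    "(pass canonical=False to override)"
                )
            off = mats["w0"][~np.eye(j, dtype=bool)]
            if off.size and not np.allclose(off, 1.0, atol=1e-12):
                raise SchemaError(
                    "canonical W0 must have unit off-diagonal "
                    "(pass canonical=False to override)"
                )

    @property
    def J(self) -> int:
        return len(self.type_labels)

    @classmethod
    def identity(cls, type_labels: Sequence) -> "WeightMatrices":
        """W1 = I, W0 = 1 - I: the weights under which every weighted
        score reduces to its classical counterpart."""
        j = len(tuple(type_labels))
        eye = np.eye(j)
        return cls(w1=eye, w0=1.0 - eye, type_labels=tuple(type_labels))


@dataclass(frozen=True)
class RandReport:
    """All Rand-type scores for one comparison, with audit quantities."""

    RI: float
    ARI: float
    wRI: float
    wPPV: float
    wNPV: float
    pair_counts: PairCounts
    s_star: float
    s_star_ref: float


def rand_index(pc: PairCounts) -> float:
    """(N11 + N00) / N: the fraction of concordant pair relationships."""
    return (pc.N11 + pc.N00) / pc.N


def adjusted_rand_index(ct: ContingencyTable) -> float:
    """Permutation-model chance-corrected Rand index.

    When both partitions are trivial the index is undefined; the
    convention here is to return 1.0 (two trivial partitions agree).
    """
    sum_cells = float(_n_pairs(ct.counts).sum())
    sum_rows = float(_n_pairs(ct.row_margins).sum())
    sum_cols = float(_n_pairs(ct.col_margins).sum())
    total = float(_n_pairs(ct.n))
    expected = sum_rows * sum_cols / total
    denom = 0.5 * (sum_rows + sum_cols) - expected
    if denom == 0.0:
        return 1.0
    return (sum_cells - expected) / denom


def _aligned_counts(ct: ContingencyTable, weights: WeightMatrices) -> np.ndarray:
    """Reorder contingency rows to the weight matrices' type order.

    Types present in the weights but absent from the table get zero
    rows; table types missing from the weights are an error.
    """
    missing = sorted(set(ct.row_labels) - set(weights.type_labels))
    if missing:
        raise SchemaError(
            f"reference types absent from the weight matrices: {missing}"
        )
    row_of = {t: k for k, t in enumerate(ct.row_labels)}
    out = np.zeros((weights.J, ct.counts.shape[1]), dtype=np.int64)
    for k, t in enumerate(weights.type_labels):
        if t in row_of:
            out[k] = ct.counts[row_of[t]]
    return out


def _pair_tallies(ct: ContingencyTable, weights: WeightMatrices, mode: str):
    """J x J matrices of pair counts by (type, type) and relationship.

    ``P1[j, j']`` counts unordered cell pairs of types (j, j') placed in
    the same cluster, ``P0`` those placed in different clusters; the
    diagonal counts within-type pairs.  Only the upper triangle
    (including the diagonal) is meaningful.
    """
    if mode not in ("C-vs-R", "R-vs-R"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = _aligned_counts(ct, weights)
    margins = counts.sum(axis=1)
    if mode == "R-vs-R":
        # the reference clustered against itself: a diagonal table
        counts = np.diag(margins)
    m = counts @ counts.T  # m[j, j'] = sum_i n_ji * n_j'i
    p1 = m.astype(float)
    np.fill_diagonal(p1, (np.diag(m) - margins) / 2.0)
    total = np.outer(margins, margins).astype(float)
    np.fill_diagonal(total, _n_pairs(margins))
    return p1, total - p1


def _upper_sum(m: np.ndarray) -> float:
    return float(np.triu(m).sum())


def weighted_agreement_score(
    ct: ContingencyTable, weights: WeightMatrices, mode: str = "C-vs-R"
) -> float:
    """S*(C, R), or S*(R, R) with ``mode='R-vs-R'``.

    Computed in O(I J^2) from the contingency table; equals the sum of
    per-pair scores over all C(n,2) cell pairs.
    """
    p1, p0 = _pair_tallies(ct, weights, mode)
    return _upper_sum(p1 * weights.w1) + _upper_sum(p0 * weights.w0)


def weighted_rand_index(
    ref: PartitionLabels, clust: PartitionLabels, weights: WeightMatrices
) -> float:
    """wRI(C, R) = S*(C, R) / S*(R, R).

    Equals RI under identity weights and lies in [0, 1] for canonical
    weights.
    """
    ct = build_contingency(ref, clust)
    s_ref = weighted_agreement_score(ct, weights, mode="R-vs-R")
    if s_ref <= 0.0:
        raise DegenerateMetricError(
            "S*(R, R) = 0: weights give the reference itself zero score"
        )
    return weighted_agreement_score(ct, weights, mode="C-vs-R") / s_ref


def weighted_predictive_values(
    ref: PartitionLabels, clust: PartitionLabels, weights: WeightMatrices
):
    """Mean pair score among co-clustered pairs (wPPV) and among
    separated pairs (wNPV).

    Under identity weights these are N11/N+1 and N00/N+0, the positive
    and negative predictive values of pair relationships.  A side with
    no pairs (e.g. all cells in one cluster leaves no separated pairs)
    is returned as NaN with a warning.
    """
    ct = build_contingency(ref, clust)
    p1, p0 = _pair_tallies(ct, weights, mode="C-vs-R")
    n_plus1 = _upper_sum(p1)
    n_plus0 = _upper_sum(p0)
    if n_plus1 > 0:
        wppv = _upper_sum(p1 * weights.w1) / n_plus1
    else:
        warnings.warn("no co-clustered pairs: wPPV is undefined (NaN)")
        wppv = float("nan")
    if n_plus0 > 0:
        wnpv = _upper_sum(p0 * weights.w0) / n_plus0
    else:
        warnings.warn("no separated pairs: wNPV is undefined (NaN)")
        wnpv = float("nan")
    return wppv, wnpv


def rand_report(
    ref: PartitionLabels,
    clust: PartitionLabels,
    weights: Optional[WeightMatrices] = None,
) -> RandReport:
    """Classical and weighted Rand-type scores for one comparison.

    With ``weights=None`` identity weights are used, so the weighted
    columns coincide with their classical counterparts.
    """
    if weights is None:
        weights = WeightMatrices.identity(ref.groups)
    ct = build_contingency(ref, clust)
    pc = pair_counts(ct)
    s_star = weighted_agreement_score(ct, weights, mode="C-vs-R")
    s_ref = weighted_agreement_score(ct, weights, mode="R-vs-R")
    if s_ref <= 0.0:
        raise DegenerateMetricError("S*(R, R) = 0 under the supplied weights")
    wppv, wnpv = weighted_predictive_values(ref, clust, weights)
    return RandReport(
        RI=rand_index(pc),
        ARI=adjusted_rand_index(ct),
        wRI=s_star / s_ref,
        wPPV=wppv,
        wNPV=wnpv,
        pair_counts=pc,
        s_star=s_star,
        s_star_ref=s_ref,
    )
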