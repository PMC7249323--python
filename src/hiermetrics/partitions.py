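"""Labelled partitions of a cell population and their cross-tabulations.

A *partition* assigns every cell to exactly one group: the reference
partition carries the known cell types, a clustering result carries the
inferred clusters.  Comparing two partitions starts from the J x I
contingency table of joint cell counts and, for pair-based indices, from
the 2x2 table of pairwise relationships (both cells in the same group, or
not, under each partition).

This module also provides a literal O(n^2) enumeration over all cell
pairs (:func:`pairwise_oracle`).  It exists so that the fast
contingency-table formulas used elsewhere can be checked against a direct
transcription of the pair-sum definitions; it is deliberately slow and
capped at small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np

from .errors import SchemaError

__all__ = [
    "PartitionLabels",
    "ContingencyTable",
    "PairCounts",
    "build_contingency",
    "pair_counts",
    "pairwise_oracle",
]

#: hard cap on the quadratic pair-enumeration oracle
ORACLE_MAX_CELLS = 5000


def _n_pairs(x):
    """Number of unordered pairs, C(x, 2), elementwise."""
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


@dataclass(frozen=True)
class PartitionLabels:
    """An assignment of each cell to exactly one group.

    Parameters
    ----------
    cell_ids
        Unique cell identifiers (coerced to ``str``).
    labels
        Group label per cell, aligned with ``cell_ids``.  Labels are
        opaque strings; numeric-looking labels are not coerced.
    """

    cell_ids: tuple
    labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "labels", tuple(str(v) for v in self.labels))
        if len(self.cell_ids) != len(self.labels):
            raise SchemaError(
                f"{len(self.cell_ids)} cell ids but {len(self.labels)} labels"
            )
        if len(self.cell_ids) < 2:
            raise SchemaError("a partition needs at least 2 cells")
        seen, dups = set(), []
        for c in self.cell_ids:
            if c in seen:
                dups.append(c)
            seen.add(c)
        if dups:
            raise SchemaError(f"duplicated cell ids: {sorted(set(dups))[:10]}")

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @cached_property
    def groups(self) -> tuple:
        """Distinct labels in first-appearance order."""
        out = []
        seen = set()
        for v in self.labels:
            if v not in seen:
                seen.add(v)
                out.append(v)
        return tuple(out)

    @cached_property
    def group_sizes(self) -> np.ndarray:
        """Cell count per group, aligned with :attr:`groups`."""
        idx = {g: k for k, g in enumerate(self.groups)}
        sizes = np.zeros(len(self.groups), dtype=np.int64)
        for v in self.labels:
            sizes[idx[v]] += 1
        return sizes

    @cached_property
    def label_by_id(self) -> dict:
        return dict(zip(self.cell_ids, self.labels))

    def relabelled(self, mapping: dict) -> "PartitionLabels":
        """New partition with each label passed through ``mapping``
        (labels absent from the mapping are kept)."""
        return PartitionLabels(
            self.cell_ids, tuple(mapping.get(v, v) for v in self.labels)
        )

    @classmethod
    def from_arrays(cls, cell_ids: Sequence, labels: Sequence) -> "PartitionLabels":
        return cls(tuple(cell_ids), tuple(labels))


@dataclass(frozen=True)
class ContingencyTable:
    """J x I joint cell counts: rows are reference types, columns clusters."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(str(v) for v in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(v) for v in self.col_labels))
        if counts.ndim != 2:
            raise SchemaError("contingency counts must be a 2-d matrix")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise SchemaError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.row_labels)} row / {len(self.col_labels)} column labels"
            )
        if (counts < 0).any():
            raise SchemaError("contingency counts must be non-negative")
        for name, labs in (("row", self.row_labels), ("column", self.col_labels)):
            if len(set(labs)) != len(labs):
                raise SchemaError(f"duplicate {name} labels in contingency table")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class PairCounts:
    """2x2 classification of all C(n,2) cell pairs.

    ``N11``: same group in both partitions; ``N10``: together in the
    reference, split by the clustering; ``N01``: split in the reference,
    together in the clustering; ``N00``: split in both.
    """

    N11: int
    N10: int
    N01: int
    N00: int

    def __post_init__(self):
        for name in ("N11", "N10", "N01", "N00"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise SchemaError(f"{name} must be a non-negative integer, got {v}")

    @property
    def N(self) -> int:
        return self.N11 + self.N10 + self.N01 + self.N00

    @property
    def N_1plus(self) -> int:
        """Pairs related in the reference."""
        return self.N11 + self.N10

    @property
    def N_plus1(self) -> int:
        """Pairs related in the clustering."""
        return self.N11 + self.N01

    @property
    def N_0plus(self) -> int:
        return self.N01 + self.N00

    @property
    def N_plus0(self) -> int:
        return self.N10 + self.N00


def build_contingency(ref: PartitionLabels, clust: PartitionLabels) -> ContingencyTable:
    """Cross-tabulate two partitions of the same cells.

    Cells are matched by id, not by position; row order follows the
    reference's first-appearance group order, column order the
    clustering's.
    """
    ref_ids, clust_ids = set(ref.cell_ids), set(clust.cell_ids)
    if ref_ids != clust_ids:
        only_ref = sorted(ref_ids - clust_ids)[:10]
        only_clust = sorted(clust_ids - ref_ids)[:10]
        msg = []
        if only_ref:
            msg.append(f"ids only in reference: {only_ref}")
        if only_clust:
            msg.append(f"ids only in clustering: {only_clust}")
        raise SchemaError("partitions cover different cells; " + "; ".join(msg))

    row_idx = {g: k for k, g in enumerate(ref.groups)}
    col_idx = {g: k for k, g in enumerate(clust.groups)}
    clust_label = clust.label_by_id
    counts = np.zeros((len(ref.groups), len(clust.groups)), dtype=np.int64)
    for cid, rlab in zip(ref.cell_ids, ref.labels):
        counts[row_idx[rlab], col_idx[clust_label[cid]]] += 1
    return ContingencyTable(counts, ref.groups, clust.groups)


def pair_counts(ct: ContingencyTable) -> PairCounts:
    """Pairwise-relationship counts from a contingency table.

    N11 = sum_ji C(n_ji,2); the margins follow from the row/column sums
    and N00 is the remainder of the C(n,2) total.
    """
    n11 = int(_n_pairs(ct.counts).sum())
    n1p = int(_n_pairs(ct.row_margins).sum())
    np1 = int(_n_pairs(ct.col_margins).sum())
    total = int(_n_pairs(ct.n))
    return PairCounts(
        N11=n11, N10=n1p - n11, N01=np1 - n11, N00=total - n1p - np1 + n11
    )


def pairwise_oracle(
    ref: PartitionLabels,
    clust: PartitionLabels,
    w1: np.ndarray,
    w0: np.ndarray,
    type_labels: Sequence,
):
    """Direct enumeration of every cell pair (test oracle).

    Walks all pairs ``1 <= k1 < k2 <= n`` literally, scoring each pair
    with ``w1[type(k1), type(k2)]`` when co-clustered and
    ``w0[type(k1), type(k2)]`` otherwise.

    Returns
    -------
    (S_star, S1_sum, S0_sum, PairCounts)
        Total weighted agreement score, its restriction to co-clustered
        pairs, its restriction to separated pairs, and the raw pair
        counts.  ``S1_sum``/``S0_sum`` are unnormalized; divide by
        ``N_plus1``/``N_plus0`` for the predictive values.
    """
    if ref.n > ORACLE_MAX_CELLS:
        raise SchemaError(
            f"pairwise_oracle is O(n^2) and capped at n={ORACLE_MAX_CELLS}; "
            "use the contingency-table operations for larger inputs"
        )
    w1 = np.asarray(w1, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    type_labels = [str(t) for t in type_labels]
    tindex = {t: k for k, t in enumerate(type_labels)}
    missing = sorted(set(ref.groups) - set(type_labels))
    if missing:
        raise SchemaError(f"reference types absent from weight labels: {missing}")

    clust_label = clust.label_by_id
    t = [tindex[v] for v in ref.labels]
    c = [clust_label[cid] for cid in ref.cell_ids]
    n = ref.n

    s_star = s1 = s0 = 0.0
    n11 = n10 = n01 = n00 = 0
    for k1 in range(n):
        for k2 in range(k1 + 1, n):
            i, j = t[k1], t[k2]
            same_r = i == j
            same_c = c[k1] == c[k2]
            if same_c:
                s = w1[i, j]
                s1 += s
                if same_r:
                    n11 += 1
                else:
                    n01 += 1
            else:
                s = w0[i, j]
                s0 += s
                if same_r:
                    n10 += 1
                else:
                    n00 += 1
            s_star += s
    return s_star, s1, s0, PairCounts(n11, n10, n01, n00)
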