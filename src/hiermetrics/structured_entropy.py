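"""Entropy-based agreement metrics, classical and hierarchy-weighted.

The mutual information MI(C, R) = H(R) - H(R|C) measures how much of the
reference partition's entropy the clustering explains; NMI divides by
the arithmetic mean of H(R) and H(C).  Both treat the J reference types
as unstructured: splitting a group of cells into two types contributes
the same entropy whether the types are near-identical subtypes or
entirely unrelated lineages.

When the reference types hang on a dendrogram, cutting it below the
(j-1)-th highest internal node yields nested partitions R_1 (one group)
through R_J (the leaf typing), and the total entropy telescopes into
stepwise conditional entropies H(R_{j+1} | R_j).  The *structured
entropy* discounts each step by how low on the tree it happens:

    H*(R) = sum_{j=1}^{J-1} d_j * H(R_{j+1} | R_j),

where d_j is the height of the internal node whose removal splits j
groups into j+1, standardized by the maximum height (so d_1 = 1).
Conditioning every step on the clustering gives H*(R|C), and

    wMI  = H*(R) - H*(R|C)
    wNMI = wMI / H*(R) * H(R) / ((H(R) + H(C)) / 2).

The first wNMI factor is the share of structured entropy explained (an
R^2-style quantity); the second balances the relative complexity of the
two partitions.  wNMI can exceed 1 when a coarse clustering merges
types separated only at a very small height; the value is reported as
computed, not clipped.

All entropies use the natural logarithm by default; the normalized
metrics are base-invariant (pass ``base`` to verify).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateMetricError, SchemaError
from .partitions import ContingencyTable, PartitionLabels, build_contingency

__all__ = [
    "ReferenceTree",
    "EntropyReport",
    "entropy",
    "mutual_information",
    "nmi",
    "cut_partitions",
    "step_weights",
    "structured_entropy",
    "structured_conditional_entropy",
    "weighted_nmi",
    "entropy_report",
]

_HEIGHT_TOL = 1e-9


def _entropy_from_counts(counts: np.ndarray, base: Optional[float] = None) -> float:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise SchemaError("entropy of an empty population is undefined")
    p = counts[counts > 0] / n
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base is not None else h


def entropy(p: PartitionLabels, base: Optional[float] = None) -> float:
    """Shannon entropy -sum_j p_j log p_j of the group proportions."""
    return _entropy_from_counts(p.group_sizes, base=base)


def mutual_information(ct: ContingencyTable, base: Optional[float] = None) -> float:
    """MI from a contingency table; zero cells are skipped."""
    counts = ct.counts.astype(float)
    n = counts.sum()
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    mask = counts > 0
    ratio = np.ones_like(counts)
    ratio[mask] = n * counts[mask] / (rows @ cols / 1.0)[mask]
    mi = float((counts[mask] / n * np.log(ratio[mask])).sum())
    mi = max(mi, 0.0)  # clip tiny negative rounding residue
    return mi / math.log(base) if base is not None else mi


def nmi(
    ref: PartitionLabels, clust: PartitionLabels, base: Optional[float] = None
) -> float:
    """MI normalized by the arithmetic mean of the two entropies."""
    h_r = entropy(ref, base=base)
    h_c = entropy(clust, base=base)
    if h_r + h_c == 0.0:
        raise DegenerateMetricError(
            "NMI undefined: both partitions are single groups"
        )
    ct = build_contingency(ref, clust)
    return mutual_information(ct, base=base) / ((h_r + h_c) / 2.0)


def _quote_newick(name: str) -> str:
    if any(ch in name for ch in "()[]{}:;,'\" \t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass(frozen=True)
class ReferenceTree:
    """Rooted ultrametric dendrogram over the J reference types.

    Stored as J-1 binary merges in a linkage-style layout: node ids
    0..J-1 are the leaves in ``leaf_names`` order, and merge row k
    creates internal node ``J + k`` joining ``children[k]`` at
    ``heights[k]`` above the leaves.  Children rows always precede their
    parent row, and heights never decrease from child to parent.
    Multifurcations are represented as chains of binary merges at the
    same height, which keeps the nested cut partitions in unit steps.
    """

    leaf_names: tuple
    children: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        names = tuple(str(v) for v in self.leaf_names)
        object.__setattr__(self, "leaf_names", names)
        j = len(names)
        if j < 2:
            raise SchemaError("a reference tree needs at least 2 leaves")
        if len(set(names)) != j:
            raise SchemaError("duplicate leaf names in reference tree")
        children = np.asarray(self.children, dtype=np.int64)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "children", children)
        object.__setattr__(self, "heights", heights)
        if children.shape != (j - 1, 2) or heights.shape != (j - 1,):
            raise SchemaError(
                f"expected {j - 1} merges for {j} leaves, got "
                f"children {children.shape}, heights {heights.shape}"
            )
        if not np.isfinite(heights).all() or (heights <= 0).any():
            raise SchemaError("internal node heights must be strictly positive")
        used = set()
        for row, (a, b) in enumerate(children):
            node = j + row
            for c in (int(a), int(b)):
                if not 0 <= c < node:
                    raise SchemaError(
                        f"merge row {row} references node {c}, which does not "
                        "precede it"
                    )
                if c in used:
                    raise SchemaError(f"node {c} is a child of two merges")
                used.add(c)
                if c >= j and heights[c - j] > heights[row] + _HEIGHT_TOL:
                    raise SchemaError(
                        "child height exceeds parent height: not a dendrogram"
                    )
        if used != set(range(2 * j - 2)):
            raise SchemaError("merges do not form a single rooted tree")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @cached_property
    def _cut_order(self) -> tuple:
        """Merge rows ranked for cutting: height descending, later rows
        (parents) first among exact ties, so cuts stay nested."""
        rows = range(self.n_leaves - 1)
        return tuple(sorted(rows, key=lambda r: (-self.heights[r], -r)))

    def step_weights(self) -> np.ndarray:
        """d_1..d_{J-1}: internal heights sorted descending over the
        maximum, so d_1 = 1 and d is non-increasing."""
        h = self.heights[list(self._cut_order)]
        return h / h[0]

    def cut_memberships(self, j: int) -> np.ndarray:
        """Group index (0..j-1) of each leaf after cutting below the
        (j-1)-th highest internal node; groups numbered by first leaf."""
        J = self.n_leaves
        if not 1 <= j <= J:
            raise SchemaError(f"cut level must be in 1..{J}, got {j}")
        parent = np.arange(2 * J - 1)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        cut = set(self._cut_order[: j - 1])
        for row in range(J - 1):
            if row in cut:
                continue
            node = J + row
            for c in self.children[row]:
                parent[find(int(c))] = node
        roots = [find(leaf) for leaf in range(J)]
        order: dict = {}
        return np.array([order.setdefault(r, len(order)) for r in roots])

    @cached_property
    def _leafsets(self) -> tuple:
        """Leaf-index set under each internal node (by merge row)."""
        J = self.n_leaves
        sets = [frozenset([k]) for k in range(J)]
        for a, b in self.children:
            sets.append(sets[int(a)] | sets[int(b)])
        return tuple(sets[J:])

    def mrca_heights(self) -> np.ndarray:
        """J x J matrix of the height of each leaf pair's lowest common
        ancestor (0 on the diagonal)."""
        J = self.n_leaves
        out = np.zeros((J, J))
        filled = np.eye(J, dtype=bool)
        # ascending height: the first node containing both leaves is the MRCA
        for row in sorted(range(J - 1), key=lambda r: (self.heights[r], r)):
            members = sorted(self._leafsets[row])
            for ai, a in enumerate(members):
                for b in members[ai + 1 :]:
                    if not filled[a, b]:
                        out[a, b] = out[b, a] = self.heights[row]
                        filled[a, b] = filled[b, a] = True
        return out

    def patristic_distances(self) -> np.ndarray:
        """Leaf-to-leaf path lengths; for an ultrametric tree this is
        twice the MRCA height."""
        return 2.0 * self.mrca_heights()

    def clades(self) -> frozenset:
        """Leaf-name sets of all non-root internal nodes; equal clade
        sets mean equal rooted topology (Robinson-Foulds distance 0)."""
        names = self.leaf_names
        return frozenset(
            frozenset(names[k] for k in self._leafsets[row])
            for row in range(self.n_leaves - 2)  # root row excluded
        )

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_linkage(cls, z: np.ndarray, leaf_names: Sequence) -> "ReferenceTree":
        """Build from a SciPy-style linkage matrix (first two columns =
        child node ids, third = merge height)."""
        z = np.asarray(z, dtype=float)
        return cls(
            leaf_names=tuple(leaf_names),
            children=z[:, :2].astype(np.int64),
            heights=z[:, 2].copy(),
        )

    def to_linkage(self) -> np.ndarray:
        """Linkage matrix (children, height, leaf count) for SciPy."""
        sizes = [1] * self.n_leaves + [len(s) for s in self._leafsets]
        z = np.zeros((self.n_leaves - 1, 4))
        z[:, :2] = self.children
        z[:, 2] = self.heights
        z[:, 3] = [sizes[self.n_leaves + r] for r in range(self.n_leaves - 1)]
        return z

    @classmethod
    def from_newick(
        cls, newick: str, ultrametric_tol: float = 1e-6
    ) -> "ReferenceTree":
        """Parse a Newick string with branch lengths.

        Node heights are reconstructed as (maximum root-to-leaf depth)
        minus root-to-node depth; leaves must be equidistant from the
        root within ``ultrametric_tol`` (relative to the tree depth).
        Multifurcations become chains of equal-height binary merges.
        """
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        root = tree.seed_node
        depth = {root: 0.0}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            length = node.edge.length
            if length is None:
                raise SchemaError(
                    "Newick tree is missing a branch length; all edges "
                    "must carry lengths to define node heights"
                )
            depth[node] = depth[node.parent_node] + float(length)
        leaves = [nd for nd in tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise SchemaError("Newick tree must have at least 2 leaves")
        total = max(depth[nd] for nd in leaves)
        scale = max(total, 1.0)
        bad = [
            nd.taxon.label if nd.taxon else "<unnamed>"
            for nd in leaves
            if abs(depth[nd] - total) > ultrametric_tol * scale
        ]
        if bad:
            raise SchemaError(
                f"tree is not ultrametric within tolerance {ultrametric_tol}: "
                f"leaves at deviating depths: {bad[:5]}"
            )
        names = []
        node_id: dict = {}
        for nd in leaves:
            if nd.taxon is None or not nd.taxon.label:
                raise SchemaError("every leaf must be labelled")
            node_id[nd] = len(names)
            names.append(nd.taxon.label)
        children, heights = [], []
        J = len(names)
        for nd in tree.postorder_internal_node_iter():
            h = total - depth[nd]
            kids = [node_id[c] for c in nd.child_nodes()]
            if len(kids) < 2:
                # unifurcation: pass the single child through
                node_id[nd] = kids[0]
                continue
            acc = kids[0]
            for other in kids[1:]:
                children.append((acc, other))
                heights.append(h)
                acc = J + len(children) - 1
            node_id[nd] = acc
        return cls(tuple(names), np.array(children), np.array(heights))

    def to_newick(self) -> str:
        """Newick string with branch lengths implied by the heights."""
        J = self.n_leaves

        def render(node: int, parent_height: float) -> str:
            if node < J:
                name, h = _quote_newick(self.leaf_names[node]), 0.0
                body = name
            else:
                row = node - J
                h = self.heights[row]
                a, b = self.children[row]
                body = f"({render(int(a), h)},{render(int(b), h)})"
            return f"{body}:{parent_height - h:.12g}"

        root = 2 * J - 2
        h = self.heights[J - 2]
        a, b = self.children[J - 2]
        return f"({render(int(a), h)},{render(int(b), h)});"


def step_weights(tree: ReferenceTree) -> np.ndarray:
    """Standardized split heights d_1..d_{J-1} (see ReferenceTree)."""
    return tree.step_weights()


def cut_partitions(tree: ReferenceTree, ref: PartitionLabels) -> list:
    """Nested partitions R_1..R_J of the cells induced by cutting the
    reference tree at 1..J groups.

    Every reference type must appear as a tree leaf; R_J reproduces the
    reference typing (with groups named by their member types).
    """
    missing = sorted(set(ref.groups) - set(tree.leaf_names))
    if missing:
        raise SchemaError(f"reference types missing from the tree: {missing}")
    leaf_idx = {name: k for k, name in enumerate(tree.leaf_names)}
    out = []
    for j in range(1, tree.n_leaves + 1):
        memb = tree.cut_memberships(j)
        group_name = {}
        for g in range(memb.max() + 1):
            members = [tree.leaf_names[k] for k in np.flatnonzero(memb == g)]
            group_name[g] = "+".join(members)
        labels = tuple(group_name[memb[leaf_idx[v]]] for v in ref.labels)
        out.append(PartitionLabels(ref.cell_ids, labels))
    return out


def structured_entropy(
    ref: PartitionLabels, tree: ReferenceTree, base: Optional[float] = None
) -> float:
    """H*(R): the d-weighted sum of stepwise entropies.

    Uses the nested-partition identity H(R_{j+1} | R_j) = H(R_{j+1}) -
    H(R_j).  With all d_j = 1 this telescopes to the plain H(R)."""
    parts = cut_partitions(tree, ref)
    h = [entropy(p, base=base) for p in parts]
    d = tree.step_weights()
    return float(sum(d[j] * (h[j + 1] - h[j]) for j in range(len(d))))


def _joint_entropy(
    a: PartitionLabels, b: PartitionLabels, base: Optional[float] = None
) -> float:
    ct = build_contingency(a, b)
    return _entropy_from_counts(ct.counts.ravel(), base=base)


def structured_conditional_entropy(
    ref: PartitionLabels,
    tree: ReferenceTree,
    clust: PartitionLabels,
    base: Optional[float] = None,
) -> float:
    """H*(R|C): every stepwise entropy additionally conditioned on the
    clustering, H(R_{j+1} | R_j, C) = H(R_{j+1} | C) - H(R_j | C)."""
    parts = cut_partitions(tree, ref)
    h_c = entropy(clust, base=base)
    cond = [_joint_entropy(p, clust, base=base) - h_c for p in parts]
    d = tree.step_weights()
    val = float(sum(d[j] * (cond[j + 1] - cond[j]) for j in range(len(d))))
    return max(val, 0.0)


def weighted_nmi(
    ref: PartitionLabels,
    tree: ReferenceTree,
    clust: PartitionLabels,
    base: Optional[float] = None,
):
    """(wMI, wNMI) of a clustering against a tree-structured reference.

    wMI = H*(R) - H*(R|C); wNMI multiplies the explained share of
    structured entropy by the complexity-balance factor
    H(R) / ((H(R) + H(C)) / 2).  wNMI may exceed 1 (see module notes).
    """
    h_star = structured_entropy(ref, tree, base=base)
    if h_star <= 0.0:
        raise DegenerateMetricError(
            "H*(R) = 0: the reference carries no structured entropy "
            "(single observed type?)"
        )
    h_r = entropy(ref, base=base)
    h_c = entropy(clust, base=base)
    if h_r + h_c == 0.0:
        raise DegenerateMetricError("both partitions are single groups")
    wmi = h_star - structured_conditional_entropy(ref, tree, clust, base=base)
    wnmi = (wmi / h_star) * (h_r / ((h_r + h_c) / 2.0))
    return wmi, wnmi


@dataclass(frozen=True)
class EntropyReport:
    """All entropy-based scores for one comparison (natural-log units)."""

    H_R: float
    H_C: float
    MI: float
    NMI: float
    H_star: float
    H_star_given_C: float
    wMI: float
    wNMI: float


def entropy_report(
    ref: PartitionLabels,
    tree: ReferenceTree,
    clust: PartitionLabels,
    base: Optional[float] = None,
) -> EntropyReport:
    h_star = structured_entropy(ref, tree, base=base)
    h_cond = structured_conditional_entropy(ref, tree, clust, base=base)
    wmi, wnmi = weighted_nmi(ref, tree, clust, base=base)
    ct = build_contingency(ref, clust)
    return EntropyReport(
        H_R=entropy(ref, base=base),
        H_C=entropy(clust, base=base),
        MI=mutual_information(ct, base=base),
        NMI=nmi(ref, clust, base=base),
        H_star=h_star,
        H_star_given_C=h_cond,
        wMI=wmi,
        wNMI=wnmi,
    )


def _conditional_entropy_direct(
    ct: ContingencyTable, base: Optional[float] = None
) -> float:
    """H(rows | columns) as the cluster-weighted average of within-column
    entropies; oracle counterpart of the joint-entropy identity."""
    n = ct.n
    total = 0.0
    for i in range(ct.counts.shape[1]):
        col = ct.counts[:, i]
        w = col.sum() / n
        if w > 0:
            total += w * _entropy_from_counts(col[col > 0], base=base)
    return total
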