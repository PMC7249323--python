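"""Synthetic hierarchical cell populations with known ground truth.

The generator draws a mean log-expression profile for the root type and
lets it drift along the reference tree: each branch adds independent
Gaussian noise per gene with variance proportional to the branch
length, so expected expression distance between types tracks their tree
distance and weight/tree recovery is well-posed.  Cells are then drawn
around their type's profile under a lognormal-rounded or negative
binomial count model.

This is deliberately not a realistic scRNA-seq simulator — there are no
library-size effects, dropout or batches — but every quantity the
estimators target (type means, the tree, pairwise type distances) is
known exactly, which is what makes it useful for testing and
benchmarking.

A single seed drives a hierarchical ``numpy.random.SeedSequence`` split
(base profile / branch drift / cell noise), so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import SchemaError
from .partitions import PartitionLabels
from .structured_entropy import ReferenceTree
from .weight_estimation import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_population",
    "perturb_clustering",
    "paired_tree",
    "random_tree",
    "random_partition",
    "random_weights",
]


def paired_tree(
    h_left: float = 0.5,
    h_right: float = 0.2,
    root_height: float = 1.0,
    names: Sequence = ("A1", "A2", "B1", "B2"),
) -> ReferenceTree:
    """Four-leaf balanced tree ((A1,A2),(B1,B2)) with sibling-pair
    heights ``h_left``/``h_right`` and the root at ``root_height``."""
    if not (0 < h_left < root_height and 0 < h_right < root_height):
        raise SchemaError("sibling heights must lie strictly below the root")
    names = tuple(names)
    if len(names) != 4:
        raise SchemaError("paired_tree needs exactly 4 leaf names")
    children = np.array([[0, 1], [2, 3], [4, 5]])
    heights = np.array([h_left, h_right, root_height])
    return ReferenceTree(names, children, heights)


def random_tree(
    leaf_names: Sequence,
    rng: np.random.Generator,
    height_range: tuple = (0.2, 1.0),
) -> ReferenceTree:
    """Random binary topology with sorted uniform merge heights."""
    names = tuple(leaf_names)
    j = len(names)
    if j < 2:
        raise SchemaError("need at least 2 leaves")
    heights = np.sort(rng.uniform(*height_range, size=j - 1))
    active = list(range(j))
    children = []
    for k in range(j - 1):
        a, b = rng.choice(len(active), size=2, replace=False)
        a, b = sorted((int(a), int(b)))
        children.append((active[a], active[b]))
        node = j + k
        active = [v for i, v in enumerate(active) if i not in (a, b)] + [node]
    return ReferenceTree(names, np.array(children), heights)


def random_partition(
    n: int, k: int, rng: np.random.Generator, prefix: str = "g", ids=None
) -> PartitionLabels:
    """Uniform random partition of n cells into exactly k non-empty
    groups (k cells are pinned to distinct groups)."""
    if k > n:
        raise SchemaError(f"cannot split {n} cells into {k} non-empty groups")
    labels = rng.integers(0, k, size=n)
    labels[rng.choice(n, size=k, replace=False)] = np.arange(k)
    cell_ids = tuple(f"cell{i + 1}" for i in range(n)) if ids is None else tuple(ids)
    return PartitionLabels(cell_ids, tuple(f"{prefix}{v + 1}" for v in labels))


def random_weights(type_labels: Sequence, rng: np.random.Generator):
    """Random canonical weights: W1 diag 1 with uniform off-diagonal,
    W0 off-diagonal 1 with uniform diagonal."""
    from .weighted_rand import WeightMatrices

    j = len(tuple(type_labels))
    w1 = np.eye(j)
    iu = np.triu_indices(j, 1)
    w1[iu] = rng.uniform(0, 1, size=len(iu[0]))
    w1 = np.triu(w1) + np.triu(w1, 1).T
    w0 = np.ones((j, j))
    np.fill_diagonal(w0, rng.uniform(0, 1, size=j))
    return WeightMatrices(w1=w1, w0=w0, type_labels=tuple(type_labels))


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated population.

    Defaults mirror a modestly sized labelled scRNA-seq study: 100
    cells per type, 1000 genes (the same order as the variable-gene set
    the estimators use), per-branch drift of 1.0 log-units per unit
    branch length, and within-type lognormal noise with sigma 0.5.
    """

    tree: ReferenceTree
    cells_per_type: int | Mapping = 100
    n_genes: int = 1000
    drift_scale: float = 1.0
    noise_scale: float = 0.5
    base_log_mean: float = 1.0
    base_log_sd: float = 1.0
    count_model: str = "lognormal"
    nb_dispersion: float = 2.0
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.seed is None:
            raise SchemaError("a seed is mandatory for reproducibility")
        if self.count_model not in ("lognormal", "negative_binomial"):
            raise SchemaError(f"unknown count model {self.count_model!r}")
        for name in ("drift_scale", "noise_scale", "base_log_sd", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise SchemaError(f"{name} must be non-negative")
        if self.n_genes < 1:
            raise SchemaError("need at least one gene")

    def cells_for(self, type_name: str) -> int:
        if isinstance(self.cells_per_type, Mapping):
            c = int(self.cells_per_type[type_name])
        else:
            c = int(self.cells_per_type)
        if c < 1:
            raise SchemaError(f"type {type_name!r} needs at least one cell")
        return c


@dataclass(frozen=True)
class SimulatedPopulation:
    """Everything the generator knows about one simulated study."""

    expression: ExpressionMatrix
    labels: PartitionLabels
    tree: ReferenceTree
    type_log_means: np.ndarray  # types x genes, leaf order
    type_distances: np.ndarray  # patristic distances, leaf order


def _node_means(cfg: SimulationConfig, rng_profile, rng_drift) -> np.ndarray:
    """Mean log1p profile of every tree node by Brownian drift."""
    tree, g = cfg.tree, cfg.n_genes
    j = tree.n_leaves
    means = np.zeros((2 * j - 1, g))
    root = 2 * j - 2
    means[root] = rng_profile.normal(cfg.base_log_mean, cfg.base_log_sd, size=g)
    node_height = np.concatenate([np.zeros(j), tree.heights])
    # parents (higher rows) before their children
    for row in range(j - 2, -1, -1):
        parent = j + row
        for child in tree.children[row]:
            child = int(child)
            branch = node_height[parent] - node_height[child]
            step = cfg.drift_scale * np.sqrt(max(branch, 0.0))
            means[child] = means[parent] + rng_drift.normal(0.0, 1.0, size=g) * step
    return means


def simulate_population(cfg: SimulationConfig) -> SimulatedPopulation:
    """Draw a labelled expression matrix from the configured tree."""
    ss = np.random.SeedSequence(cfg.seed)
    s_profile, s_drift, s_noise = ss.spawn(3)
    rng_profile = np.random.default_rng(s_profile)
    rng_drift = np.random.default_rng(s_drift)
    rng_noise = np.random.default_rng(s_noise)

    tree = cfg.tree
    means = _node_means(cfg, rng_profile, rng_drift)
    leaf_means = means[: tree.n_leaves]

    columns, cell_ids, labels = [], [], []
    for t, name in enumerate(tree.leaf_names):
        n_cells = cfg.cells_for(name)
        profile = leaf_means[t]
        for c in range(n_cells):
            if cfg.count_model == "lognormal":
                eps = rng_noise.normal(0.0, cfg.noise_scale, size=cfg.n_genes)
                x = np.rint(np.clip(np.expm1(profile + eps), 0.0, None))
            else:
                mu = np.clip(np.expm1(profile), 1e-8, None)
                p = cfg.nb_dispersion / (cfg.nb_dispersion + mu)
                x = rng_noise.negative_binomial(cfg.nb_dispersion, p).astype(float)
            columns.append(x)
            cell_ids.append(f"{name}.{c + 1:03d}")
            labels.append(name)
    expr = ExpressionMatrix(
        values=np.stack(columns, axis=1),
        gene_ids=tuple(f"g{i + 1:04d}" for i in range(cfg.n_genes)),
        cell_ids=tuple(cell_ids),
    )
    return SimulatedPopulation(
        expression=expr,
        labels=PartitionLabels(tuple(cell_ids), tuple(labels)),
        tree=tree,
        type_log_means=leaf_means,
        type_distances=tree.patristic_distances(),
    )


_MODES = ("merge_siblings", "merge_distant", "split_type", "random_swap")


def _closest_pair(tree: ReferenceTree, groups, extreme: str):
    h = tree.mrca_heights()
    idx = [tree.leaf_names.index(g) for g in groups]
    best = None
    for ai, a in enumerate(idx):
        for b in idx[ai + 1 :]:
            key = h[a, b]
            if (
                best is None
                or (extreme == "min" and key < best[0])
                or (extreme == "max" and key > best[0])
            ):
                best = (key, tree.leaf_names[a], tree.leaf_names[b])
    return best[1], best[2]


def perturb_clustering(
    ref: PartitionLabels,
    mode: str,
    tree: Optional[ReferenceTree] = None,
    magnitude: int = 0,
    seed: Optional[int] = None,
    pair: Optional[tuple] = None,
) -> PartitionLabels:
    """A clustering with one controlled, named error.

    ``magnitude`` cells are moved; 0 returns the reference unchanged.
    Modes: ``merge_siblings`` / ``merge_distant`` move cells of one
    type into the cluster of the closest / most distant other type
    (``pair=(src, dst)`` overrides the choice); ``split_type`` carves
    ``magnitude`` cells of the largest type into a new cluster;
    ``random_swap`` reassigns random cells to random other clusters and
    requires a seed.  Without a seed, the moved cells are the type's
    first cells in input order.
    """
    if mode not in _MODES:
        raise SchemaError(f"unknown perturbation mode {mode!r}; pick from {_MODES}")
    if magnitude < 0:
        raise SchemaError("magnitude must be non-negative")
    if magnitude == 0:
        return PartitionLabels(ref.cell_ids, ref.labels)
    labels = list(ref.labels)
    rng = np.random.default_rng(seed) if seed is not None else None

    def pick_cells(of_type: str, count: int):
        idx = [k for k, v in enumerate(labels) if v == of_type]
        if count > len(idx):
            raise SchemaError(
                f"cannot move {count} cells from type {of_type!r} "
                f"({len(idx)} available)"
            )
        if rng is None:
            return idx[:count]
        return list(rng.choice(idx, size=count, replace=False))

    if mode in ("merge_siblings", "merge_distant"):
        if len(ref.groups) < 2:
            raise SchemaError(f"{mode} needs at least 2 reference types")
        if pair is None:
            if tree is None:
                raise SchemaError(f"{mode} needs the reference tree (or a pair=)")
            missing = sorted(set(ref.groups) - set(tree.leaf_names))
            if missing:
                raise SchemaError(f"reference types missing from tree: {missing}")
            a, b = _closest_pair(
                tree, ref.groups, "min" if mode == "merge_siblings" else "max"
            )
            sizes = dict(zip(ref.groups, ref.group_sizes))
            src, dst = (a, b) if sizes[a] >= sizes[b] else (b, a)
        else:
            src, dst = (str(pair[0]), str(pair[1]))
            for t in (src, dst):
                if t not in ref.groups:
                    raise SchemaError(f"type {t!r} not present in the reference")
        for k in pick_cells(src, magnitude):
            labels[k] = dst
    elif mode == "split_type":
        sizes = dict(zip(ref.groups, ref.group_sizes))
        target = max(ref.groups, key=lambda t: sizes[t])
        if magnitude >= sizes[target]:
            raise SchemaError(
                f"splitting {magnitude} cells would empty type {target!r}"
            )
        for k in pick_cells(target, magnitude):
            labels[k] = f"{target}_split"
    else:  # random_swap
        if rng is None:
            raise SchemaError("random_swap requires a seed")
        if len(ref.groups) < 2:
            raise SchemaError("random_swap needs at least 2 groups")
        moved = rng.choice(ref.n, size=min(magnitude, ref.n), replace=False)
        for k in moved:
            others = [g for g in ref.groups if g != labels[k]]
            labels[k] = others[int(rng.integers(len(others)))]
    return PartitionLabels(ref.cell_ids, tuple(labels))
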