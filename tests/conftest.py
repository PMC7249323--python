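"""Shared fixtures: small hand-checkable populations and weight setups."""

import numpy as np
import pytest

import hiermetrics as hm


def partition_from_sizes(sizes: dict) -> hm.PartitionLabels:
    """A partition with the given cells-per-type, ids ``<type>.<k>``."""
    ids, labels = [], []
    for t, s in sizes.items():
        for k in range(s):
            ids.append(f"{t}.{k}")
            labels.append(t)
    return hm.PartitionLabels(tuple(ids), tuple(labels))


def random_comparison(rng, max_n=200, max_j=8, max_i=10):
    """A random reference/clustering pair with random canonical weights."""
    n = int(rng.integers(10, max_n + 1))
    j = int(rng.integers(2, min(max_j, n) + 1))
    i = int(rng.integers(1, min(max_i, n) + 1))
    ref = hm.random_partition(n, j, rng, prefix="t")
    clust = hm.random_partition(n, i, rng, prefix="c", ids=ref.cell_ids)
    weights = hm.random_weights(ref.groups, rng)
    return ref, clust, weights


@pytest.fixture
def four_cell():
    """Two types x two crossing clusters with partial-credit weights.

    All six cell pairs are checkable by hand: S* = 3.4, wRI = 17/30,
    wPPV = 0.5, wNPV = 0.6.
    """
    ref = hm.PartitionLabels(("c1", "c2", "c3", "c4"), ("A", "A", "B", "B"))
    clust = hm.PartitionLabels(("c1", "c2", "c3", "c4"), ("1", "2", "1", "2"))
    weights = hm.WeightMatrices(
        w1=np.array([[1.0, 0.5], [0.5, 1.0]]),
        w0=np.array([[0.2, 1.0], [1.0, 0.2]]),
        type_labels=("A", "B"),
    )
    return ref, clust, weights


@pytest.fixture
def eight_cell():
    """Types A1(2), A2(2), B(4) on tree ((A1,A2):0.2, B):1.0 with the
    clustering that merges A1 and A2: H* = 1.1 ln2, wMI = ln2,
    wNMI = 12/11, NMI = 0.8."""
    ids = tuple(f"c{i}" for i in range(8))
    ref = hm.PartitionLabels(ids, ("A1", "A1", "A2", "A2", "B", "B", "B", "B"))
    tree = hm.ReferenceTree(
        ("A1", "A2", "B"), np.array([[0, 1], [3, 2]]), np.array([0.2, 1.0])
    )
    clust = hm.PartitionLabels(ids, ("x", "x", "x", "x", "y", "y", "y", "y"))
    return ref, tree, clust


@pytest.fixture
def caterpillar5():
    """Five types splitting one at a time at distinct heights."""
    return hm.ReferenceTree(
        ("T1", "T2", "T3", "T4", "T5"),
        np.array([[0, 1], [5, 2], [6, 3], [7, 4]]),
        np.array([0.25, 0.5, 0.75, 1.0]),
    )
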