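"""Entropy, MI/NMI, nested tree cuts, and the structured-entropy metrics."""

import math

import numpy as np
import pytest

import hiermetrics as hm
from hiermetrics.errors import DegenerateMetricError, SchemaError
from hiermetrics.structured_entropy import _conditional_entropy_direct

from conftest import partition_from_sizes, random_comparison

LN2 = math.log(2)


def labelled(labels):
    ids = tuple(f"c{i}" for i in range(len(labels)))
    return hm.PartitionLabels(ids, tuple(labels))


class TestEntropyAndMI:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ("AAAA", 0.0),
            ("AABB", LN2),
            ("ABCC", 1.5 * LN2),  # proportions (1/4, 1/4, 1/2)
        ],
    )
    def test_entropy(self, labels, expected):
        assert hm.entropy(labelled(labels)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[2, 0], [0, 2]], LN2),
            ([[1, 1], [1, 1]], 0.0),
            ([[2, 0], [2, 0], [0, 4]], LN2),  # the 8-cell fixture's table
        ],
    )
    def test_mutual_information(self, counts, expected):
        ct = hm.ContingencyTable(
            np.array(counts),
            tuple(f"r{i}" for i in range(len(counts))),
            tuple(f"c{i}" for i in range(len(counts[0]))),
        )
        assert hm.mutual_information(ct) == pytest.approx(expected, abs=1e-12)

    def test_nmi_examples(self, eight_cell):
        ref, _, clust = eight_cell
        assert hm.nmi(ref, clust) == pytest.approx(0.8, abs=1e-12)
        assert hm.nmi(ref, ref) == pytest.approx(1.0)
        balanced = labelled("AABB")
        independent = labelled("1212")
        independent = hm.PartitionLabels(balanced.cell_ids, independent.labels)
        assert hm.nmi(balanced, independent) == pytest.approx(0.0, abs=1e-12)

    def test_nmi_undefined_for_two_trivial_partitions(self):
        triv = labelled("AAA")
        with pytest.raises(DegenerateMetricError):
            hm.nmi(triv, triv)


class TestTreeCuts:
    def test_two_leaf_tree(self):
        tree = hm.ReferenceTree(("A", "B"), np.array([[0, 1]]), np.array([1.0]))
        ref = labelled("AABB")
        parts = hm.cut_partitions(tree, ref)
        assert [len(p.groups) for p in parts] == [1, 2]
        assert parts[1].labels == ref.labels

    def test_three_leaf_topology_forced_cut(self, eight_cell):
        ref, tree, _ = eight_cell
        parts = hm.cut_partitions(tree, ref)
        assert parts[1].groups == ("A1+A2", "B")

    def test_caterpillar_cuts_split_one_group_per_level(self, caterpillar5):
        ref = partition_from_sizes({t: 3 for t in caterpillar5.leaf_names})
        parts = hm.cut_partitions(caterpillar5, ref)
        assert [len(p.groups) for p in parts] == [1, 2, 3, 4, 5]
        for coarse, fine in zip(parts, parts[1:]):
            # each level refines the previous by splitting exactly one group
            mapping = {}
            for cid in ref.cell_ids:
                mapping.setdefault(fine.label_by_id[cid], set()).add(
                    coarse.label_by_id[cid]
                )
            assert all(len(v) == 1 for v in mapping.values())

    def test_missing_type_listed(self, caterpillar5):
        ref = labelled(["T1", "T1", "NOPE", "NOPE"])
        with pytest.raises(SchemaError, match="NOPE"):
            hm.cut_partitions(caterpillar5, ref)


class TestStepWeights:
    @pytest.mark.parametrize(
        "heights, expected",
        [
            ([1.0, 0.2], [1.0, 0.2]),
            ([5.0, 1.0], [1.0, 0.2]),  # scale invariance
        ],
    )
    def test_standardization(self, heights, expected):
        tree = hm.ReferenceTree(
            ("A", "B", "C"), np.array([[0, 1], [3, 2]]), np.array(heights[::-1])
        )
        assert hm.step_weights(tree) == pytest.approx(expected)

    def test_single_split(self):
        tree = hm.ReferenceTree(("A", "B"), np.array([[0, 1]]), np.array([3.0]))
        assert hm.step_weights(tree) == pytest.approx([1.0])

    def test_nonpositive_heights_rejected(self):
        with pytest.raises(SchemaError, match="positive"):
            hm.ReferenceTree(("A", "B"), np.array([[0, 1]]), np.array([0.0]))


class TestStructuredEntropy:
    def test_eight_cell_value(self, eight_cell):
        ref, tree, _ = eight_cell
        assert hm.structured_entropy(ref, tree) == pytest.approx(
            1.1 * LN2, abs=1e-12
        )

    def test_unit_weights_recover_plain_entropy(self, caterpillar5):
        flat = hm.ReferenceTree(
            caterpillar5.leaf_names,
            caterpillar5.children,
            np.ones(4),  # every split at the same height: all d_j = 1
        )
        ref = partition_from_sizes({"T1": 1, "T2": 2, "T3": 3, "T4": 4, "T5": 5})
        assert hm.structured_entropy(ref, flat) == pytest.approx(
            hm.entropy(ref), abs=1e-12
        )

    def test_conditional_examples(self, eight_cell):
        ref, tree, clust = eight_cell
        assert hm.structured_conditional_entropy(ref, tree, ref) == pytest.approx(
            0.0, abs=1e-12
        )
        assert hm.structured_conditional_entropy(ref, tree, clust) == pytest.approx(
            0.1 * LN2, abs=1e-12
        )
        lumped = hm.PartitionLabels(ref.cell_ids, ("z",) * 8)
        assert hm.structured_conditional_entropy(
            ref, tree, lumped
        ) == pytest.approx(hm.structured_entropy(ref, tree), abs=1e-12)


class TestWeightedNMI:
    def test_eight_cell_values(self, eight_cell):
        ref, tree, clust = eight_cell
        wmi, wnmi = hm.weighted_nmi(ref, tree, clust)
        assert wmi == pytest.approx(LN2, abs=1e-12)
        assert wnmi == pytest.approx(12 / 11, abs=1e-12)

    def test_self_comparison_is_one(self, eight_cell):
        ref, tree, _ = eight_cell
        _, wnmi = hm.weighted_nmi(ref, tree, ref)
        assert wnmi == pytest.approx(1.0, abs=1e-12)

    def test_single_observed_type_raises(self, eight_cell):
        _, tree, _ = eight_cell
        ref = labelled(["B"] * 4)
        clust = hm.PartitionLabels(ref.cell_ids, ("1", "1", "2", "2"))
        with pytest.raises(DegenerateMetricError):
            hm.weighted_nmi(ref, tree, clust)


class TestInvariants:
    def _random_tree_and_labels(self, rng):
        j = int(rng.integers(2, 7))
        names = tuple(f"T{k}" for k in range(j))
        tree = hm.random_tree(names, rng)
        n = int(rng.integers(j + 2, 60))
        ref = hm.random_partition(n, j, rng, prefix="T0")  # placeholder
        # map the generated group names onto the tree leaves
        mapping = dict(zip(ref.groups, names))
        ref = ref.relabelled(mapping)
        i = int(rng.integers(1, min(8, n + 1)))
        clust = hm.random_partition(n, i, rng, prefix="c", ids=ref.cell_ids)
        return tree, ref, clust

    def test_chain_decomposition_and_nested_identity(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            tree, ref, clust = self._random_tree_and_labels(rng)
            parts = hm.cut_partitions(tree, ref)
            h = [hm.entropy(p) for p in parts]
            steps = [h[j + 1] - h[j] for j in range(len(h) - 1)]
            assert sum(steps) == pytest.approx(h[-1], abs=1e-12)
            # entropy-difference step equals the direct conditional entropy
            for j in range(len(parts) - 1):
                ct = hm.build_contingency(parts[j + 1], parts[j])
                assert _conditional_entropy_direct(ct) == pytest.approx(
                    steps[j], abs=1e-12
                )

    def test_joint_identity_matches_percluster_oracle(self):
        # H(R|C) via the joint-entropy identity H(R) - MI equals the
        # cluster-weighted average of within-cluster entropies
        rng = np.random.default_rng(22)
        for _ in range(50):
            _, ref, clust = self._random_tree_and_labels(rng)
            ct = hm.build_contingency(ref, clust)
            h_cond = hm.entropy(ref) - hm.mutual_information(ct)
            assert _conditional_entropy_direct(ct) == pytest.approx(
                h_cond, abs=1e-10
            )

    def test_unit_step_weights_degrade_to_classical(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            tree, ref, clust = self._random_tree_and_labels(rng)
            flat = hm.ReferenceTree(
                tree.leaf_names, tree.children, np.ones(tree.n_leaves - 1)
            )
            wmi, wnmi = hm.weighted_nmi(ref, flat, clust)
            ct = hm.build_contingency(ref, clust)
            assert wmi == pytest.approx(hm.mutual_information(ct), abs=1e-12)
            assert wnmi == pytest.approx(hm.nmi(ref, clust), abs=1e-12)

    def test_wmi_bounds_and_refinement_monotonicity(self):
        rng = np.random.default_rng(24)
        for _ in range(30):
            tree, ref, clust = self._random_tree_and_labels(rng)
            h_star = hm.structured_entropy(ref, tree)
            wmi, _ = hm.weighted_nmi(ref, tree, clust)
            assert -1e-12 <= wmi <= h_star + 1e-12
            # splitting one cluster never increases H*(R|C)
            before = hm.structured_conditional_entropy(ref, tree, clust)
            sizes = dict(zip(clust.groups, clust.group_sizes))
            big = max(clust.groups, key=lambda g: sizes[g])
            idx = [k for k, v in enumerate(clust.labels) if v == big]
            labels = list(clust.labels)
            for k in idx[: len(idx) // 2]:
                labels[k] = f"{big}_b"
            refined = hm.PartitionLabels(clust.cell_ids, tuple(labels))
            after = hm.structured_conditional_entropy(ref, tree, refined)
            assert after <= before + 1e-12

    def test_log_base_invariance_of_normalized_metrics(self, eight_cell):
        ref, tree, clust = eight_cell
        assert hm.nmi(ref, clust, base=2) == pytest.approx(
            hm.nmi(ref, clust), abs=1e-12
        )
        _, wnmi_e = hm.weighted_nmi(ref, tree, clust)
        _, wnmi_2 = hm.weighted_nmi(ref, tree, clust, base=2)
        assert wnmi_2 == pytest.approx(wnmi_e, abs=1e-12)

    def test_tied_heights_cut_order_does_not_change_entropies(self):
        # two internal nodes at exactly the same height: the d values are
        # equal, so the structured entropy must not depend on cut order
        names = ("a", "b", "c", "d")
        t1 = hm.ReferenceTree(
            names, np.array([[0, 1], [2, 3], [4, 5]]), np.array([0.4, 0.4, 1.0])
        )
        t2 = hm.ReferenceTree(
            names, np.array([[2, 3], [0, 1], [4, 5]]), np.array([0.4, 0.4, 1.0])
        )
        ref = partition_from_sizes({"a": 2, "b": 3, "c": 4, "d": 5})
        assert hm.structured_entropy(ref, t1) == pytest.approx(
            hm.structured_entropy(ref, t2), abs=1e-12
        )

    def test_multifurcation_as_equal_height_steps(self):
        # a trifurcation encoded as two merges at the same height
        tree = hm.ReferenceTree(
            ("a", "b", "c"), np.array([[0, 1], [3, 2]]), np.array([1.0, 1.0])
        )
        assert hm.step_weights(tree) == pytest.approx([1.0, 1.0])
        ref = labelled("aabbcc")
        assert hm.structured_entropy(ref, tree) == pytest.approx(
            hm.entropy(ref), abs=1e-12
        )
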