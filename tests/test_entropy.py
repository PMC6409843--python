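"""Tests for structure entropy evaluation and minimization.

Expected values marked "hand evaluation" were derived term by term from
the entropy definition, independently of the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ssecluster as sc
from ssecluster.entropy import MergeCache

from conftest import random_weighted_graph

# hand evaluation for the unit barbell (two triangles + bridge, 2e = 14):
# each triangle: intra = (4/14)*log2(7/2) + (3/14)*log2(7/3)
# boundary: 2 * (1/14) * log2(14/7)
BARBELL_INTRA = 2 * ((4 / 14) * math.log2(7 / 2) + (3 / 14) * math.log2(7 / 3))
BARBELL_BOUNDARY = 2 * (1 / 14) * math.log2(2)
BARBELL_TOTAL = BARBELL_INTRA + BARBELL_BOUNDARY  # ~1.6995 bits


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.25] * 4, 2.0),
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_hand_cases(self, p, expected):
        assert sc.shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_distribution(self):
        with pytest.raises(sc.InputError):
            sc.shannon_entropy([0.5, 0.4])
        with pytest.raises(sc.InputError):
            sc.shannon_entropy([1.5, -0.5])

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=20))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_by_log_support(self, weights):
        p = np.asarray(weights) / np.sum(weights)
        H = sc.shannon_entropy(p)
        assert -1e-9 <= H <= math.log2(len(p)) + 1e-9


class TestOneDimensionalEntropy:
    def test_regular_graph_gives_log_n(self):
        ring = sc.generate_toy_graph("ring", 7)
        assert sc.one_dimensional_entropy(ring) == pytest.approx(math.log2(7))

    def test_star_with_three_leaves(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        G = sc.CellGraph(["hub", "a", "b", "c"], W)
        expected = -(3 / 6) * math.log2(3 / 6) - 3 * (1 / 6) * math.log2(1 / 6)
        assert sc.one_dimensional_entropy(G) == pytest.approx(expected, abs=1e-12)

    def test_equals_singleton_partition_entropy(self, barbell6):
        singles = sc.Partition(np.arange(6))
        assert sc.one_dimensional_entropy(barbell6) == pytest.approx(
            sc.partition_entropy(barbell6, singles).total_bits, abs=1e-12
        )


class TestPartitionEntropy:
    def test_triangle_single_community(self):
        tri = sc.generate_toy_graph("ring", 3)  # 3-ring is a triangle
        rep = sc.partition_entropy(tri, sc.Partition(np.zeros(3, dtype=int)))
        assert rep.total_bits == pytest.approx(math.log2(3))
        assert rep.boundary_term_bits == 0.0

    def test_barbell_two_triangle_partition(self, barbell6):
        rep = sc.partition_entropy(barbell6, sc.Partition(np.array([0, 0, 0, 1, 1, 1])))
        assert rep.total_bits == pytest.approx(BARBELL_TOTAL, abs=1e-9)
        assert rep.intra_term_bits == pytest.approx(BARBELL_INTRA, abs=1e-9)
        assert rep.boundary_term_bits == pytest.approx(BARBELL_BOUNDARY, abs=1e-9)

    def test_whole_graph_equals_one_dimensional(self, barbell6):
        whole = sc.Partition(np.zeros(6, dtype=int))
        assert sc.partition_entropy(barbell6, whole).total_bits == pytest.approx(
            sc.one_dimensional_entropy(barbell6), abs=1e-12
        )

    def test_decomposition_identity_random_graphs(self):
        for seed in range(10):
            G = random_weighted_graph(9, seed)
            labels = np.random.default_rng(seed).integers(0, 3, 9)
            rep = sc.partition_entropy(G, sc.Partition.from_raw(labels))
            assert rep.total_bits == pytest.approx(
                rep.intra_term_bits + rep.boundary_term_bits, abs=1e-10
            )
            assert rep.intra_term_bits >= -1e-12
            assert rep.boundary_term_bits >= -1e-12

    def test_scale_invariance(self):
        G = random_weighted_graph(10, 3)
        labels = sc.Partition.from_raw(np.arange(10) % 3)
        h1 = sc.partition_entropy(G, labels).total_bits
        G2 = sc.CellGraph(G.node_ids, G.W * 1e3)
        assert sc.partition_entropy(G2, labels).total_bits == pytest.approx(h1, abs=1e-9)

    def test_length_mismatch_rejected(self, barbell6):
        with pytest.raises(sc.InputError):
            sc.partition_entropy(barbell6, sc.Partition(np.array([0, 0, 1, 1])))


class TestMergeDelta:
    def test_merging_last_two_recovers_one_dimensional_gap(self, barbell6):
        P = sc.Partition(np.array([0, 0, 0, 1, 1, 1]))
        delta = sc.merge_delta(barbell6, P, 0, 1)
        expected = sc.one_dimensional_entropy(barbell6) - sc.partition_entropy(
            barbell6, P
        ).total_bits
        assert delta == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_full_recomputation(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for trial in range(50):
            G = random_weighted_graph(12, trial)
            labels = sc.Partition.from_raw(rng.integers(0, 4, 12))
            cache = MergeCache(G, labels)
            L = labels.num_communities
            for a in range(L):
                for b in range(a + 1, L):
                    merged = labels.labels.copy()
                    merged[merged == b] = a
                    full = (
                        sc.partition_entropy(G, sc.Partition.from_raw(merged)).total_bits
                        - sc.partition_entropy(G, labels).total_bits
                    )
                    inc = sc.merge_delta(G, labels, a, b, cache)
                    worst = max(worst, abs(inc - full))
        assert worst < 1e-10

    def test_merging_disconnected_cliques_raises_entropy(self, two_triangles):
        P = sc.Partition(np.array([0, 0, 0, 1, 1, 1]))
        assert sc.merge_delta(two_triangles, P, 0, 1) > 0

    def test_invalid_pair_rejected(self, barbell6):
        P = sc.Partition(np.array([0, 0, 0, 1, 1, 1]))
        with pytest.raises(sc.InputError):
            sc.merge_delta(barbell6, P, 0, 0)
        with pytest.raises(sc.InputError):
            sc.merge_delta(barbell6, P, 0, 5)


class TestMinimizeEntropy:
    def test_two_disjoint_triangles_found_exactly(self, two_triangles):
        part, rep = sc.minimize_entropy(two_triangles)
        np.testing.assert_array_equal(part.labels, [0, 0, 0, 1, 1, 1])

    def test_barbell_recovers_triangles(self, barbell6):
        part, rep = sc.minimize_entropy(barbell6)
        np.testing.assert_array_equal(part.labels, [0, 0, 0, 1, 1, 1])
        assert rep.total_bits == pytest.approx(BARBELL_TOTAL, abs=1e-9)

    def test_planted_two_block_graph_exact_recovery(self):
        n = 20
        labels = np.repeat([0, 1], 10)
        U = np.triu(np.where(labels[:, None] == labels[None, :], 1.0, 0.05), k=1)
        G = sc.CellGraph([f"n{i}" for i in range(n)], U + U.T)
        part, _ = sc.minimize_entropy(G)
        assert sc.ari(labels, part.labels) == pytest.approx(1.0)

    def test_never_beats_and_matches_oracle_on_small_graphs(self):
        graphs = [
            sc.generate_toy_graph("two_cliques", 4),
            sc.generate_toy_graph("barbell", 4),
            sc.generate_toy_graph("ring", 8),
        ]
        for G in graphs:
            _, rep = sc.minimize_entropy(G)
            _, h_star = sc.exhaustive_min_entropy(G)
            assert rep.total_bits >= h_star - 1e-12
            assert rep.total_bits == pytest.approx(h_star, abs=1e-9)

    def test_components_never_merged(self):
        G = sc.generate_toy_graph("two_cliques", 5)
        part, _ = sc.minimize_entropy(G)
        left = set(part.labels[:5])
        right = set(part.labels[5:])
        assert left.isdisjoint(right)

    def test_entropy_never_above_singletons(self):
        for seed in range(8):
            G = random_weighted_graph(14, seed)
            _, rep = sc.minimize_entropy(G)
            assert rep.total_bits <= sc.one_dimensional_entropy(G) + 1e-10

    def test_permutation_equivariance(self):
        G = random_weighted_graph(12, 5)
        part, _ = sc.minimize_entropy(G)
        perm = np.random.default_rng(1).permutation(12)
        G2 = sc.CellGraph(
            [G.node_ids[i] for i in perm], G.W[np.ix_(perm, perm)]
        )
        part2, _ = sc.minimize_entropy(G2)
        assert sc.ari(part.labels[perm], part2.labels) == pytest.approx(1.0)

    def test_no_edges_rejected(self):
        with pytest.raises((sc.GraphError, sc.InputError)):
            sc.build_cell_graph(np.zeros((3, 3)))


class TestExhaustiveOracle:
    def test_single_edge_two_nodes(self):
        G = sc.build_cell_graph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        part, h = sc.exhaustive_min_entropy(G)
        # both partitions of 2 nodes give H = 1 bit; fewer communities wins
        assert part.num_communities == 1
        assert h == pytest.approx(1.0)

    def test_two_triangles_partition(self, two_triangles):
        part, _ = sc.exhaustive_min_entropy(two_triangles)
        np.testing.assert_array_equal(part.labels, [0, 0, 0, 1, 1, 1])

    def test_size_limit(self):
        G = random_weighted_graph(11, 0)
        with pytest.raises(sc.SizeError):
            sc.exhaustive_min_entropy(G)
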