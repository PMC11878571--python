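"""Graph metrics against brute-force oracles and structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from longconn.metrics import (
    Partition,
    eigenvector_centrality,
    global_efficiency,
    global_metrics,
    local_efficiency,
    mean_degree,
    modularity,
    modularity_q,
    node_strength,
    participation_coefficient,
    transitivity,
)


class TestTrivialCases:
    def test_strength_zero_graph(self):
        assert np.array_equal(node_strength(np.zeros((3, 3))), np.zeros(3))

    def test_strength_triangle(self, triangle):
        assert np.array_equal(node_strength(triangle), [2, 2, 2])

    def test_mean_degree_triangle(self, triangle):
        assert mean_degree(triangle) == 2.0

    def test_mean_degree_star(self, star4):
        assert mean_degree(star4) == 1.5

    def test_transitivity_triangle_is_one(self, triangle):
        assert transitivity(triangle) == pytest.approx(1.0)

    def test_transitivity_star_is_zero(self, star4):
        assert transitivity(star4) == 0.0

    def test_transitivity_small_graph_is_zero(self):
        assert transitivity(np.zeros((2, 2))) == 0.0

    def test_global_efficiency_complete_k5(self):
        w = np.ones((5, 5)) - np.eye(5)
        assert global_efficiency(w) == pytest.approx(1.0)

    def test_global_efficiency_isolated_nodes(self):
        assert global_efficiency(np.zeros((2, 2))) == 0.0

    def test_local_efficiency_triangle(self, triangle):
        assert local_efficiency(triangle) == pytest.approx([1, 1, 1])

    def test_local_efficiency_star(self, star4):
        assert np.array_equal(local_efficiency(star4), np.zeros(4))

    def test_eigencentrality_complete_k4_uniform(self):
        w = np.ones((4, 4)) - np.eye(4)
        assert eigenvector_centrality(w) == pytest.approx([0.5] * 4)

    def test_eigencentrality_star_hub_largest(self, star4):
        v = eigenvector_centrality(star4)
        assert v[0] > v[1:].max()

    def test_eigencentrality_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            eigenvector_centrality(np.zeros((3, 3)))

    def test_participation_all_within_own_community(self, triangle):
        pc = participation_coefficient(triangle, np.zeros(3, dtype=int))
        assert pc == pytest.approx([0, 0, 0])

    def test_participation_even_split_two_communities(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        pc = participation_coefficient(w, np.array([0, 0, 1]))
        assert pc[0] == pytest.approx(0.5)

    def test_modularity_single_community_q_zero(self):
        w = np.ones((4, 4)) - np.eye(4)
        assert modularity_q(w, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_modularity_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty network"):
            modularity(np.zeros((4, 4)))

    def test_global_metrics_empty_rejected(self):
        with pytest.raises(ValueError, match="empty network"):
            global_metrics(np.zeros((4, 4)))


class TestOracleAgreement:
    def test_strength_random_graphs(self, rng):
        for _ in range(20):
            w = oracles.random_weighted_graph(rng, 6)
            assert node_strength(w) == pytest.approx(oracles.strength_oracle(w), abs=1e-12)

    def test_transitivity_random_graphs(self, rng):
        for _ in range(20):
            w = oracles.random_weighted_graph(rng, 7)
            assert transitivity(w) == pytest.approx(
                oracles.transitivity_oracle(w), abs=1e-10
            )

    def test_global_efficiency_random_graphs(self, rng):
        for _ in range(20):
            w = oracles.random_weighted_graph(rng, 7, density=0.5)
            assert global_efficiency(w) == pytest.approx(
                oracles.global_efficiency_oracle(w), abs=1e-10
            )

    def test_local_efficiency_random_graphs(self, rng):
        for _ in range(10):
            w = oracles.random_weighted_graph(rng, 6, density=0.6)
            assert local_efficiency(w) == pytest.approx(
                oracles.local_efficiency_oracle(w), abs=1e-10
            )

    def test_participation_random_graphs_random_partitions(self, rng):
        for _ in range(20):
            w = oracles.random_weighted_graph(rng, 7)
            labels = rng.integers(0, 3, size=7)
            labels = np.unique(labels, return_inverse=True)[1]
            part = Partition(labels=labels, resolution_gamma=1.0, seed=0)
            assert participation_coefficient(w, part) == pytest.approx(
                oracles.participation_oracle(w, labels), abs=1e-12
            )

    def test_eigencentrality_random_graphs(self, rng):
        for _ in range(20):
            w = oracles.random_weighted_graph(rng, 5, density=0.9)
            assert eigenvector_centrality(w) == pytest.approx(
                oracles.eigenvector_centrality_oracle(w), abs=1e-9
            )

    def test_louvain_recovers_disconnected_triangles(self):
        w = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        part, q = modularity(w, seed=1)
        labels = part.labels
        assert len({labels[0], labels[3]}) == 2
        assert labels[0] == labels[1] == labels[2]
        _, best_q = oracles.best_modularity_oracle(w)
        assert q == pytest.approx(best_q, abs=1e-12)

    def test_q_matches_formula_reevaluation(self, rng):
        for _ in range(10):
            w = oracles.random_weighted_graph(rng, 8)
            part, q = modularity(w, seed=3)
            assert q == pytest.approx(
                oracles.modularity_q_oracle(w, part.labels), abs=1e-12
            )


class TestInvariants:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 8))
    def test_permutation_equivariance(self, seed, n):
        rng = np.random.default_rng(seed)
        w = oracles.random_weighted_graph(rng, n)
        perm = rng.permutation(n)
        wp = w[np.ix_(perm, perm)]
        assert node_strength(wp) == pytest.approx(node_strength(w)[perm], abs=1e-12)
        assert transitivity(wp) == pytest.approx(transitivity(w), abs=1e-10)
        assert global_efficiency(wp) == pytest.approx(global_efficiency(w), abs=1e-10)
        if w.sum() > 0:
            assert eigenvector_centrality(wp) == pytest.approx(
                eigenvector_centrality(w)[perm], abs=1e-8
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.floats(0.1, 10.0))
    def test_weight_scaling(self, seed, k):
        rng = np.random.default_rng(seed)
        w = oracles.random_weighted_graph(rng, 6, density=0.9)
        if w.sum() == 0:
            return
        assert node_strength(k * w) == pytest.approx(k * node_strength(w), rel=1e-9)
        assert transitivity(k * w) == pytest.approx(transitivity(w), rel=1e-9)
        labels = np.zeros(6, dtype=int)
        labels[3:] = 1
        assert participation_coefficient(k * w, labels) == pytest.approx(
            participation_coefficient(w, labels), abs=1e-12
        )
        assert eigenvector_centrality(k * w) == pytest.approx(
            eigenvector_centrality(w), abs=1e-9
        )

    def test_modularity_deterministic_for_fixed_seed(self, rng):
        w = oracles.random_weighted_graph(rng, 8)
        p1, q1 = modularity(w, seed=42)
        p2, q2 = modularity(w, seed=42)
        assert np.array_equal(p1.labels, p2.labels) and q1 == q2

    def test_global_metrics_composition(self, rng):
        w = oracles.random_weighted_graph(rng, 8, density=0.9)
        gm = global_metrics(w, seed=7)
        assert gm.mean_degree == pytest.approx(mean_degree(w))
        assert gm.transitivity == pytest.approx(transitivity(w))
        assert gm.global_efficiency == pytest.approx(global_efficiency(w))
        _, q = modularity(w, seed=7)
        assert gm.modularity_q == pytest.approx(q)
        assert 0.0 <= gm.transitivity <= 1.0
        assert gm.global_efficiency >= 0.0
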