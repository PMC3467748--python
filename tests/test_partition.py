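"""Unlabeled-set partitioning: distance filter, similarity network,
label propagation and the LP/LN/WN split."""

import math

import numpy as np
import pytest

from pudi.partition import (
    build_similarity_network,
    extract_reliable_negatives,
    init_priors,
    partition_genes,
    partition_unlabeled,
    positive_representative,
    propagate,
    propagate_direct,
)


class TestPositiveRepresentative:
    def test_single_positive_unit_mode_normalizes(self):
        v = np.array([[3.0, 4.0]])
        assert np.allclose(positive_representative(v, mode="unit"), [0.6, 0.8])

    def test_two_positives_unit_mode(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(
            positive_representative(v, mode="unit"), [0.7071, 0.7071], atol=1e-4
        )

    def test_mean_mode_is_the_centroid(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(positive_representative(v), [0.5, 0.5])

    def test_all_zero_positives_error(self):
        with pytest.raises(ValueError, match="zero norm"):
            positive_representative(np.zeros((3, 4)))


class TestReliableNegatives:
    def test_hand_worked_one_dimensional_case(self):
        pr = np.array([1.0])
        u = np.array([[0.0], [0.9], [2.5]])
        rn = extract_reliable_negatives(pr, u, ["a", "b", "c"])
        # distances 1, 0.1, 1.5; mean 0.8667; strictly greater -> {a, c}
        assert rn == {"a", "c"}

    def test_all_genes_at_the_representative(self):
        pr = np.array([1.0, 2.0])
        u = np.tile(pr, (4, 1))
        assert extract_reliable_negatives(pr, u, list("abcd")) == set()

    def test_single_gene_equals_the_mean(self):
        pr = np.array([0.0])
        assert extract_reliable_negatives(pr, np.array([[5.0]]), ["a"]) == set()


class TestSimilarityNetwork:
    def test_identical_pair_has_unit_weight(self):
        net = build_similarity_network(["a", "b"], np.array([[1.0], [1.0]]), q=1)
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_q1_collinear_points_union_graph(self):
        net = build_similarity_network(
            ["x0", "x1", "x10"], np.array([[0.0], [1.0], [10.0]]), q=1
        )
        w = net.weights.toarray()
        assert w[0, 1] > 0 and w[1, 2] > 0  # union keeps 1-10 via node 10
        assert w[0, 2] == 0.0

    def test_q1_duplicate_clusters_stay_separate(self):
        net = build_similarity_network(
            list("abcd"), np.array([[0.0], [0.0], [5.0], [5.0]]), q=1
        )
        w = net.weights.toarray()
        assert w[0, 1] == pytest.approx(1.0)
        assert w[2, 3] == pytest.approx(1.0)
        assert w[0, 2] == w[0, 3] == w[1, 2] == w[1, 3] == 0.0

    def test_q_at_least_node_count_gives_complete_graph(self, caplog):
        net = build_similarity_network(
            ["a", "b", "c"], np.array([[0.0], [1.0], [2.0]]), q=10
        )
        assert (net.weights.toarray() > 0).sum() == 6  # all off-diagonal

    def test_symmetric_zero_diagonal(self, rng):
        x = rng.normal(size=(30, 5))
        net = build_similarity_network([f"g{i}" for i in range(30)], x, q=4)
        w = net.weights.toarray()
        assert np.allclose(w, w.T)
        assert np.all(np.diag(w) == 0)


class TestPriors:
    def test_hand_worked_sizes(self):
        nodes = [f"p{i}" for i in range(3)] + [f"n{i}" for i in range(6)]
        g0 = init_priors(nodes, {f"p{i}" for i in range(3)}, {f"n{i}" for i in range(6)})
        assert np.all(g0[:3] == 1.0)
        assert np.all(g0[3:] == pytest.approx(-0.5))

    def test_equal_sizes_give_minus_one(self):
        g0 = init_priors(["p", "n"], {"p"}, {"n"})
        assert g0.tolist() == [1.0, -1.0]

    def test_mass_conservation_for_random_sizes(self, rng):
        """Positive and negative prior mass cancel by construction; the
        float sum is zero to rounding."""
        for _ in range(50):
            n_p = int(rng.integers(1, 40))
            n_rn = int(rng.integers(1, 60))
            n_u = int(rng.integers(0, 30))
            nodes = (
                [f"p{i}" for i in range(n_p)]
                + [f"r{i}" for i in range(n_rn)]
                + [f"u{i}" for i in range(n_u)]
            )
            g0 = init_priors(nodes, {f"p{i}" for i in range(n_p)},
                             {f"r{i}" for i in range(n_rn)})
            assert g0[:n_p].sum() == n_p  # exact: integer-valued floats
            assert math.fsum(g0) == pytest.approx(0.0, abs=1e-12 * n_p)

    def test_empty_rn_is_fatal_with_guidance(self):
        with pytest.raises(ValueError, match="reliable negative"):
            init_priors(["p"], {"p"}, set())


class TestPropagation:
    def test_edgeless_graph_steady_state_is_scaled_prior(self):
        import scipy.sparse as sp

        from pudi.partition import SimilarityNetwork

        net = SimilarityNetwork(["a", "b"], sp.csr_matrix((2, 2)), 1, 1.0)
        g0 = np.array([1.0, -1.0])
        scores, _, converged = propagate(net, g0, alpha=0.8)
        assert converged
        assert np.allclose(scores, 0.2 * g0)

    def test_two_node_unit_edge_closed_form(self):
        net = build_similarity_network(["a", "b"], np.array([[0.0], [0.0]]), q=1)
        scores, _, _ = propagate(net, np.array([1.0, 0.0]), alpha=0.8, epsilon=1e-12)
        assert np.allclose(scores, [0.5556, 0.4444], atol=1e-4)

    def test_small_alpha_limit_recovers_prior(self):
        net = build_similarity_network(["a", "b"], np.array([[0.0], [0.0]]), q=1)
        g0 = np.array([1.0, -0.5])
        scores, _, _ = propagate(net, g0, alpha=1e-9, epsilon=1e-15)
        assert np.allclose(scores, g0, atol=1e-6)

    def test_alpha_out_of_range_rejected(self):
        net = build_similarity_network(["a", "b"], np.array([[0.0], [1.0]]), q=1)
        for alpha in (0.0, 1.0, -0.3, 2.0):
            with pytest.raises(ValueError):
                propagate(net, np.zeros(2), alpha=alpha)

    def test_iterative_matches_direct_solve(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 80))
            x = rng.normal(size=(n, 4))
            net = build_similarity_network([f"g{i}" for i in range(n)], x, q=5)
            g0 = rng.normal(size=n)
            iterative, _, conv = propagate(net, g0, epsilon=1e-13, max_iter=5000)
            assert conv
            direct = propagate_direct(net, g0)
            assert np.max(np.abs(iterative - direct)) < 1e-8

    def test_l1_update_differences_contract(self, rng):
        n = 40
        x = rng.normal(size=(n, 3))
        net = build_similarity_network([f"g{i}" for i in range(n)], x, q=4)
        from pudi.partition import _normalised_adjacency

        s = _normalised_adjacency(net.weights)
        g0 = rng.normal(size=n)
        g = g0.copy()
        diffs = []
        for _ in range(30):
            g_next = 0.8 * (s @ g) + 0.2 * g0
            diffs.append(np.abs(g_next - g).sum())
            g = g_next
        assert all(b <= a + 1e-12 for a, b in zip(diffs, diffs[1:]))


class TestPartitionUnlabeled:
    def test_hand_worked_split(self):
        lp, ln, wn = partition_unlabeled({"a": 0.3, "b": -0.1, "c": -0.6})
        assert (lp, ln, wn) == ({"a"}, {"c"}, {"b"})

    def test_all_positive_scores(self):
        lp, ln, wn = partition_unlabeled({"a": 0.2, "b": 0.1})
        assert lp == {"a", "b"} and ln == set() and wn == set()

    def test_all_zero_scores_go_to_likely_negative(self):
        lp, ln, wn = partition_unlabeled({"a": 0.0, "b": 0.0})
        assert lp == set() and ln == {"a", "b"} and wn == set()


class TestPartitionGenes:
    def test_partition_is_disjoint_and_exhaustive(self, rng):
        n_p, n_u = 10, 50
        x_p = rng.normal(loc=1.0, size=(n_p, 6))
        x_u = rng.normal(loc=0.0, size=(n_u, 6))
        p_ids = [f"p{i}" for i in range(n_p)]
        u_ids = [f"u{i}" for i in range(n_u)]
        res = partition_genes(p_ids, u_ids, x_p, x_u, q=5)
        union = (
            res.reliable_negative
            | res.likely_positive
            | res.likely_negative
            | res.weak_negative
        )
        assert union == set(u_ids)
        sets = [res.reliable_negative, res.likely_positive,
                res.likely_negative, res.weak_negative]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_hidden_positives_score_above_true_negatives(self, rng):
        """Sign separation: genes drawn from the positive model but placed
        in U get higher steady-state scores than background genes."""
        n_p, n_hidden, n_neg = 15, 8, 40
        pos_model = lambda k: rng.normal(loc=1.2, scale=0.6, size=(k, 5))
        neg_model = lambda k: rng.normal(loc=-0.5, scale=0.6, size=(k, 5))
        x_p = pos_model(n_p)
        x_u = np.vstack([pos_model(n_hidden), neg_model(n_neg)])
        u_ids = [f"h{i}" for i in range(n_hidden)] + [f"n{i}" for i in range(n_neg)]
        res = partition_genes([f"p{i}" for i in range(n_p)], u_ids, x_p, x_u, q=5)
        hidden_scores = [res.scores[f"h{i}"] for i in range(n_hidden)]
        neg_scores = [res.scores[f"n{i}"] for i in range(n_neg)]
        assert np.mean(hidden_scores) > np.mean(neg_scores)
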