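"""Evaluation metrics: routing, concentration, alignment, communities."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import ortho_group

from hyperembed.evaluation import (
    align_to_reference,
    community_concentration,
    consensus_dimension,
    detect_geometric_communities,
    empirical_connection_curve,
    greedy_routing,
    partition_quality,
)
from hyperembed.geometry import ModelParams, sample_uniform_sphere
from hyperembed.hyperbolic import HyperbolicCoordinates, to_hyperbolic
from tests.conftest import make_sd_network


def coords_from(positions, kappa, params):
    return to_hyperbolic(positions, np.asarray(kappa, float), params)


class TestGreedyRouting:
    def test_complete_graph_perfect(self, rng):
        n = 12
        A = sp.csr_matrix(nx.to_scipy_sparse_array(nx.complete_graph(n)))
        params = ModelParams.from_mean_degree(n, 1, 2.0, n - 1.0)
        pos = sample_uniform_sphere(n, 1, rng)
        res = greedy_routing(A, coords_from(pos, np.full(n, 5.0), params), rng=rng)
        assert res.success_rate == 1.0
        assert res.mean_stretch == 1.0
        assert res.n_pairs == n * (n - 1)

    def test_cycle_with_exact_circle_coordinates(self, rng):
        # C8 with true D=1 positions: greedy always takes the right direction
        n = 8
        A = sp.csr_matrix(nx.to_scipy_sparse_array(nx.cycle_graph(n)))
        ang = 2 * np.pi * np.arange(n) / n
        pos = np.column_stack([np.cos(ang), np.sin(ang)])
        params = ModelParams.from_mean_degree(n, 1, 2.0, 2.0)
        res = greedy_routing(A, coords_from(pos, np.full(n, 2.0), params), rng=rng)
        assert res.success_rate == 1.0
        assert res.mean_stretch == 1.0

    def test_failure_detected_on_adversarial_coordinates(self, rng):
        # a path with scrambled coordinates cannot route every pair greedily
        n = 20
        A = sp.csr_matrix(nx.to_scipy_sparse_array(nx.path_graph(n)))
        perm = np.random.default_rng(0).permutation(n)
        ang = 2 * np.pi * perm / n
        pos = np.column_stack([np.cos(ang), np.sin(ang)])
        params = ModelParams.from_mean_degree(n, 1, 2.0, 2.0)
        res = greedy_routing(A, coords_from(pos, np.full(n, 2.0), params), rng=rng)
        assert res.success_rate < 1.0

    def test_true_coordinates_navigate_well(self):
        nd, pos_true, kappa_true, _, net = make_sd_network(seed=21, N=500, D=2, beta=6.0,
                                                           gamma=2.7, mean_degree=10.0)
        res = greedy_routing(nd.adjacency, coords_from(pos_true, kappa_true, net.params),
                             n_pairs=2000, rng=np.random.default_rng(1))
        assert res.success_rate > 0.7
        assert res.mean_stretch >= 1.0


class TestCommunityConcentration:
    def test_full_fraction_approaches_unity(self, rng):
        # n_g = N - 1 (self excluded): rho = (N_l - 1)/(N - 1) * N/N_l -> 1
        N = 60
        pos = sample_uniform_sphere(N, 2, rng)
        labels = np.arange(N) % 3
        res = community_concentration(pos, labels, fraction=1.0)
        exact = (20 - 1) / (N - 1) * (N / 20)
        np.testing.assert_allclose(res.rho_node_comm, exact, atol=1e-12)
        np.testing.assert_allclose(res.rho_node_comm, 1.0, atol=5 / N)

    def test_random_labels_unenriched(self, rng):
        # labels independent of geometry: the enrichment rho has mean ~ 1
        # (the raw co-membership fraction sits at its 1/N_C baseline)
        pos = sample_uniform_sphere(2000, 2, rng)
        labels = rng.integers(0, 4, 2000)
        res = community_concentration(pos, labels)
        assert res.rho_random == pytest.approx(0.25)
        assert res.c_C == pytest.approx(1.0, abs=0.05)
        raw_fraction = res.c_C / 4.0  # undo the N/N_l enrichment factor
        assert raw_fraction == pytest.approx(res.rho_random, abs=0.02)

    def test_two_antipodal_caps_exact_enrichment(self, rng):
        # 50 nodes tightly around each pole; top-10% neighborhoods are pure
        pole = np.array([0.0, 0.0, 1.0])
        from hyperembed.generator import sample_in_cap

        a = sample_in_cap(pole, 0.2, 2, 50, rng)
        b = sample_in_cap(-pole, 0.2, 2, 50, rng)
        pos = np.vstack([a, b])
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        res = community_concentration(pos, labels, fraction=0.1)
        assert res.c_C == pytest.approx(2.0)

    def test_invariant_under_rotation(self, rng):
        pos = sample_uniform_sphere(300, 2, rng)
        labels = rng.integers(0, 3, 300)
        Q = ortho_group.rvs(3, random_state=5)
        r1 = community_concentration(pos, labels).c_C
        r2 = community_concentration(pos @ Q, labels).c_C
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_singleton_community_warned_and_skipped(self, rng):
        pos = sample_uniform_sphere(20, 1, rng)
        labels = np.r_[np.zeros(19, int), np.array([1])]
        with pytest.warns(UserWarning):
            res = community_concentration(pos, labels)
        assert np.isnan(res.rho_node_comm[-1])


class TestAlignment:
    def test_self_alignment_is_identity(self, rng):
        pos = sample_uniform_sphere(100, 2, rng)
        aligned, r, disp = align_to_reference(pos, pos)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert disp == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_known_rotation(self, seed, rng):
        pos = sample_uniform_sphere(500, 2, rng)
        Q = ortho_group.rvs(3, random_state=seed)
        aligned, r, disp = align_to_reference(pos @ Q, pos)
        np.testing.assert_allclose(r, 1.0, atol=1e-10)
        assert disp < 1e-6  # arccos amplifies round-off near zero separation

    def test_unrelated_point_sets_uncorrelated(self):
        a = sample_uniform_sphere(1000, 2, np.random.default_rng(1))
        b = sample_uniform_sphere(1000, 2, np.random.default_rng(2))
        _, r, _ = align_to_reference(a, b)
        assert np.all(np.abs(r) < 0.15)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            align_to_reference(sample_uniform_sphere(10, 1, rng), sample_uniform_sphere(10, 2, rng))


class TestConnectionCurve:
    def test_matches_gravity_law_on_ground_truth(self):
        nd, pos_true, kappa_true, _, net = make_sd_network(seed=13, N=600, D=2, beta=4.0,
                                                           gamma=2.7, mean_degree=8.0)
        curve = empirical_connection_curve(nd.adjacency, pos_true, kappa_true, net.params, n_bins=15)
        big = curve[curve.n_pairs >= 200]
        sigma = np.sqrt(big.p_theory * (1 - big.p_theory) / big.n_pairs)
        within = np.abs(big.fraction - big.p_theory) <= 3 * np.maximum(sigma, 1e-3)
        assert within.mean() >= 0.9

    def test_fraction_trend_non_increasing(self):
        nd, pos_true, kappa_true, _, net = make_sd_network(seed=14, N=600, D=1, beta=3.0,
                                                           gamma=2.7, mean_degree=8.0)
        curve = empirical_connection_curve(nd.adjacency, pos_true, kappa_true, net.params, n_bins=12)
        big = curve[curve.n_pairs >= 300].reset_index(drop=True)
        # isotonic trend check: allow binomial wiggle, compare smoothed ends
        k = len(big) // 3
        assert big.fraction[:k].mean() > big.fraction[-k:].mean()


class TestGeometricCommunities:
    def test_antipodal_caps_perfectly_recovered(self, rng):
        from hyperembed.generator import sample_in_cap

        pole = np.array([0.0, 0.0, 1.0])
        pos = np.vstack([sample_in_cap(pole, 0.3, 2, 40, rng),
                         sample_in_cap(-pole, 0.3, 2, 40, rng)])
        truth = np.r_[np.zeros(40, int), np.ones(40, int)]
        labels = detect_geometric_communities(pos, 2)
        from sklearn.metrics import normalized_mutual_info_score

        assert normalized_mutual_info_score(truth, labels) == pytest.approx(1.0)

    def test_singleton_limit(self, rng):
        pos = sample_uniform_sphere(15, 1, rng)
        labels = detect_geometric_communities(pos, 15)
        assert np.unique(labels).size == 15

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_geometric_communities(sample_uniform_sphere(5, 1, rng), 6)


class TestPartitionQuality:
    def test_identical_labels_full_information(self, rng):
        nd, _, _, _, _ = make_sd_network(seed=15, N=200, D=1, beta=2.5, mean_degree=6.0)
        labels = rng.integers(0, 3, nd.n_nodes)
        _, nmi = partition_quality(nd.adjacency, labels, labels)
        assert nmi == pytest.approx(1.0)

    def test_two_triangles_modularity_half(self):
        G = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        A = sp.csr_matrix(nx.to_scipy_sparse_array(G))
        labels = np.array([0, 0, 0, 1, 1, 1])
        Q, _ = partition_quality(A, labels, labels)
        assert Q == pytest.approx(0.5)

    def test_matches_networkx_modularity(self, rng):
        nd, _, _, _, _ = make_sd_network(seed=16, N=300, D=1, beta=3.0, mean_degree=6.0)
        labels = rng.integers(0, 4, nd.n_nodes)
        Q, _ = partition_quality(nd.adjacency, labels, labels)
        G = nx.from_scipy_sparse_array(nd.adjacency)
        comms = [set(np.flatnonzero(labels == c)) for c in range(4)]
        assert Q == pytest.approx(nx.community.modularity(G, comms), abs=1e-12)

    def test_random_labels_on_er_graph_zero_modularity(self):
        qs = []
        for seed in range(50):
            G = nx.gnp_random_graph(60, 0.15, seed=seed)
            A = sp.csr_matrix(nx.to_scipy_sparse_array(G))
            labels = np.random.default_rng(seed).integers(0, 3, 60)
            Q, _ = partition_quality(A, labels, labels)
            qs.append(Q)
        # random partitions carry no modular signal beyond O(1/m) bias
        assert abs(np.mean(qs)) < 0.02

    def test_constant_partition_warns(self):
        G = nx.complete_graph(5)
        A = sp.csr_matrix(nx.to_scipy_sparse_array(G))
        with pytest.warns(UserWarning):
            _, nmi = partition_quality(A, np.zeros(5, int), np.arange(5))
        assert nmi == 0.0


class TestConsensus:
    def test_unanimous_vote(self):
        metrics = {1: {"p_s": 0.4, "c_C": 1.5}, 2: {"p_s": 0.8, "c_C": 3.0}, 3: {"p_s": 0.6, "c_C": 2.0}}
        res = consensus_dimension(metrics)
        assert res.dimension == 2 and not res.unresolved

    def test_stretch_votes_for_minimum(self):
        metrics = {1: {"stretch": 1.1, "p_s": 0.2}, 2: {"stretch": 1.4, "p_s": 0.9}}
        res = consensus_dimension(metrics)
        assert res.votes["stretch"] == 1
        assert res.votes["p_s"] == 2
        assert res.unresolved and res.dimension is None

    def test_requires_two_dimensions(self):
        with pytest.raises(ValueError):
            consensus_dimension({2: {"p_s": 0.5}})
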