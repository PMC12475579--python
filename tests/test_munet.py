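import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import _oracles
from mupool import munet, preprocess, synthetic
from mupool.munet import (
    MIAdjacency,
    build_network,
    gc_mi,
    link_communities,
    mi_matrix,
    network_metrics,
    percolation_threshold,
)

FS = 2048.0


def adjacency(n, pairs):
    A = np.zeros((n, n))
    for i, j, w in pairs:
        A[i, j] = A[j, i] = w
    return MIAdjacency(A, [f"MU{k:02d}" for k in range(n)])


class TestGaussianCopulaMI:
    def closed_form(self, rho):
        return -0.5 * np.log(1 - rho**2)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_bivariate_gaussian_closed_form(self, rho, rng):
        a = rng.standard_normal(5000)
        b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal(5000)
        assert gc_mi(a, b) == pytest.approx(self.closed_form(rho), abs=0.02)

    def test_independent_pairs_near_zero(self, rng):
        vals = [
            gc_mi(rng.standard_normal(5000), rng.standard_normal(5000))
            for _ in range(5)
        ]
        assert np.mean(vals) < 0.01

    def test_monotone_transform_invariance_exact(self, rng):
        x = rng.standard_normal(500)
        y = 0.6 * x + rng.standard_normal(500)
        assert gc_mi(x, np.exp(y)) == gc_mi(x, y)
        assert gc_mi(np.cbrt(x), y) == gc_mi(x, y)

    def test_symmetry(self, rng):
        x, y = rng.standard_normal((2, 500))
        assert gc_mi(x, y) == pytest.approx(gc_mi(y, x), abs=1e-12)

    def test_constant_or_short_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            gc_mi(np.ones(500), rng.standard_normal(500))
        with pytest.raises(ValueError):
            gc_mi(rng.standard_normal(50), rng.standard_normal(50))

    def test_estimator_bias_small_at_n5000(self):
        # copula estimator converges to the Gaussian closed form
        biases = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.standard_normal(5000)
            b = 0.6 * a + 0.8 * r.standard_normal(5000)
            biases.append(gc_mi(a, b) - self.closed_form(0.6))
        assert abs(np.mean(biases)) < 0.01


class TestMIMatrix:
    def test_duplicated_column_hits_clip_ceiling(self, rng):
        X = rng.standard_normal((1000, 3))
        X[:, 2] = X[:, 1]
        adj = mi_matrix(X, decimate_to_hz=None)
        cap = -0.5 * np.log1p(-(1 - 1e-12) ** 2)
        assert adj.matrix[1, 2] == pytest.approx(cap)
        assert adj.matrix[0, 1] < 1.0

    def test_column_reordering_permutes_output(self, rng):
        X = rng.standard_normal((800, 4)) + rng.standard_normal((800, 1))
        adj = mi_matrix(X, decimate_to_hz=None).matrix
        perm = np.array([2, 0, 3, 1])
        adj_p = mi_matrix(X[:, perm], decimate_to_hz=None).matrix
        np.testing.assert_allclose(adj_p, adj[np.ix_(perm, perm)], atol=1e-9)

    def test_independent_pool_has_low_mi(self):
        vals = []
        for seed in range(10):
            sim = synthetic.generate_cohort(
                n_trials=1, seed=700 + seed,
                pool=synthetic.PoolSpec(
                    n_units=5, common_gain=0.0, noise_gain=0.05
                ),
            )
            tr = sim.cohort.trials[0]
            spikes = preprocess.binarize(tr.trains, *sim.analysis_window_s)
            Z = preprocess.detrend_standardize(preprocess.smooth_rates(spikes))
            adj = mi_matrix(Z)
            off = adj.matrix[np.triu_indices(5, 1)]
            vals.append(off.mean())
        assert np.mean(vals) < 0.02


class TestPercolation:
    def test_uniform_weights_keep_everything(self):
        adj = adjacency(3, [(0, 1, 0.4), (1, 2, 0.4), (0, 2, 0.4)])
        res = percolation_threshold(adj)
        assert res.threshold == 0.4
        assert len(res.retained_edges) == 3
        assert res.spanning

    def test_chain_with_weak_extra_edge(self):
        adj = adjacency(4, [(0, 1, 0.9), (1, 2, 0.8), (2, 3, 0.7), (0, 3, 0.1)])
        res = percolation_threshold(adj)
        assert res.threshold == 0.7
        assert len(res.retained_edges) == 3
        assert (0, 3, 0.1) not in res.retained_edges

    def test_fragmentation_curve_non_increasing(self, rng):
        A = _oracles.random_graph_adjacency(8, rng)
        res = percolation_threshold(MIAdjacency(A, list("abcdefgh")))
        assert np.all(np.diff(res.giant_component_sizes) <= 0)

    def test_all_zero_adjacency_warns_empty(self):
        with pytest.warns(UserWarning):
            res = percolation_threshold(adjacency(3, []))
        assert res.retained_edges == []

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for k in range(50):
            n = int(rng.integers(3, 9))
            A = _oracles.random_graph_adjacency(n, rng, p_edge=rng.uniform(0.3, 0.9))
            if not (A > 0).any():
                continue
            ours = percolation_threshold(
                MIAdjacency(A, [str(i) for i in range(n)])
            ).threshold
            assert ours == pytest.approx(_oracles.percolation_scan(A))


class TestLinkCommunities:
    def test_single_clique_is_one_community(self):
        A = np.full((4, 4), 0.8)
        np.fill_diagonal(A, 0.0)
        adj = MIAdjacency(A, list("abcd"))
        net = build_network(adj, percolation_threshold(adj))
        comms = link_communities(net)
        assert comms.n_components == 1
        assert comms.first_component_fraction == 100.0

    def test_two_triangles_sharing_a_node(self):
        adj = adjacency(
            5,
            [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9),
             (0, 3, 0.9), (3, 4, 0.9), (0, 4, 0.9)],
        )
        net = build_network(adj, percolation_threshold(adj))
        comms = link_communities(net)
        assert comms.n_components == 2
        # shared node overlaps both communities
        assert comms.membership[:, 0].sum() == 2
        assert comms.first_component_fraction == pytest.approx(60.0)

    def test_cut_maximizes_partition_density_exhaustively(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 12:
            n = int(rng.integers(4, 7))
            A = _oracles.random_graph_adjacency(n, rng, p_edge=0.5)
            edges = [
                (i, j, A[i, j])
                for i, j in zip(*np.triu_indices(n, 1))
                if A[i, j] > 0
            ]
            if not 2 <= len(edges) <= 8:
                continue
            net = munet.MUNetwork([str(v) for v in range(n)], edges,
                                  2 * len(edges) / (n * (n - 1)))
            comms = link_communities(net)
            # independent scan over every dendrogram cut
            D = munet._link_similarity_matrix(edges, n)
            Z = linkage(squareform(D, checks=False), method="single")
            best = max(
                _oracles.partition_density(
                    fcluster(Z, t=h, criterion="distance"), edges
                )
                for h in np.unique(np.concatenate([[0.0], Z[:, 2]]))
            )
            assert comms.partition_density == pytest.approx(best)
            checked += 1

    def test_every_connected_unit_has_a_community(self, rng):
        A = _oracles.random_graph_adjacency(7, rng, p_edge=0.5)
        adj = MIAdjacency(A, [str(i) for i in range(7)])
        net = build_network(adj, percolation_threshold(adj))
        comms = link_communities(net)
        connected = {v for e in net.edges for v in e[:2]}
        for v in connected:
            assert comms.membership[:, v].sum() >= 1

    def test_edgeless_network_rejected(self):
        net = munet.MUNetwork(["a", "b"], [], 0.0)
        with pytest.raises(ValueError):
            link_communities(net)


class TestNetworkMetrics:
    def test_complete_graph_density_one(self):
        A = np.full((5, 5), 0.3)
        np.fill_diagonal(A, 0.0)
        adj = MIAdjacency(A, list("abcde"))
        net = build_network(adj, percolation_threshold(adj))
        assert net.density == pytest.approx(1.0)

    def test_density_by_edge_count(self):
        adj = adjacency(4, [(0, 1, 0.5), (1, 2, 0.5), (2, 3, 0.5)])
        net = build_network(adj, percolation_threshold(adj))
        assert net.density == pytest.approx(0.5)  # 3 of 6 possible edges

    def test_empty_network_density_zero(self):
        with pytest.warns(UserWarning):
            perc = percolation_threshold(adjacency(3, []))
        net = build_network(adjacency(3, []), perc)
        m = network_metrics(net, None)
        assert m["density"] == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            network_metrics(munet.MUNetwork(["a"], [], 0.0), None)


class TestEndToEndNetworkStability:
    def test_common_driven_pool_dense_and_stable(self):
        # strongly common-driven pools give dense, trial-stable networks
        # with one dominant community holding most units
        strong = synthetic.PoolSpec(common_gain=0.40, noise_gain=0.02)
        densities = []
        fractions = []
        sds = []
        for seed in range(8):
            sim = synthetic.generate_cohort(
                n_trials=3, seed=300 + seed, frozen_input=True, pool=strong
            )
            per_trial = []
            for tr in sim.cohort.trials:
                spikes = preprocess.binarize(tr.trains, *sim.analysis_window_s)
                Z = preprocess.detrend_standardize(preprocess.smooth_rates(spikes))
                adj = mi_matrix(Z)
                net = build_network(adj, percolation_threshold(adj))
                per_trial.append(net.density)
                fractions.append(
                    link_communities(net).first_component_fraction
                )
            densities.append(np.mean(per_trial))
            sds.append(np.std(per_trial))
        assert np.mean(densities) > 0.6
        assert np.mean(sds) < 0.1
        assert np.mean(fractions) > 80.0
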