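"""Weighted graph metrics against closed-form cases and independent oracles."""

import numpy as np
import pytest

import gaitconn as gc
from gaitconn.connectivity import WindowGrid
from gaitconn.network import GLOBAL_METRIC_NAMES


def floyd_warshall_reference(w):
    """Independent all-pairs shortest-path oracle (triple loop, 1/w lengths)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def random_graph(rng, n=8, density=0.6):
    w = rng.uniform(0.05, 1.0, size=(n, n))
    w *= rng.uniform(size=(n, n)) < density
    w = np.triu(w, 1)
    w = w + w.T
    return gc.WeightedGraph(w)


class TestThreshold:
    def test_half_of_strongest_rule(self):
        w = np.array(
            [[0, 0.8, 0.3, 0.0],
             [0.8, 0, 0.41, 0.4],
             [0.3, 0.41, 0, 0.2],
             [0.0, 0.4, 0.2, 0]]
        )
        out = gc.threshold_edges(gc.WeightedGraph(w), 0.5)
        assert out.weights[0, 1] == 0.8  # kept, above 0.4
        assert out.weights[1, 2] == 0.41  # kept, just above
        assert out.weights[1, 3] == 0.0  # removed, equal to cut
        assert out.weights[0, 2] == 0.0

    def test_equal_weights_all_kept(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        out = gc.threshold_edges(gc.WeightedGraph(w), 0.5)
        assert np.array_equal(out.weights, w)

    def test_zero_graph_stays_zero(self):
        out = gc.threshold_edges(gc.WeightedGraph(np.zeros((4, 4))), 0.5)
        assert np.all(out.weights == 0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gc.threshold_edges(gc.WeightedGraph(np.zeros((3, 3))), 1.0)


def complete_graph(n):
    w = np.ones((n, n))
    np.fill_diagonal(w, 0.0)
    return gc.WeightedGraph(w)


class TestClosedFormGraphs:
    def test_k4_global_metrics(self):
        gm = gc.global_metrics(complete_graph(4))
        assert gm.global_efficiency == pytest.approx(1.0)
        assert gm.char_path_length == pytest.approx(1.0)
        assert gm.transitivity == pytest.approx(1.0)

    def test_k4_local_metrics(self):
        lm = gc.local_metrics(complete_graph(4))
        assert np.allclose(lm.strength, 3.0)
        assert np.allclose(lm.clustering_coeff, 1.0)
        assert np.allclose(lm.local_efficiency, 1.0)
        assert np.allclose(lm.eigenvector_centrality, 0.5)

    def test_star_graph_has_zero_transitivity(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        gm = gc.global_metrics(gc.WeightedGraph(w))
        assert gm.transitivity == 0.0

    def test_isolated_node_gets_zero_local_metrics(self):
        w = np.zeros((5, 5))
        w[:4, :4] = complete_graph(4).weights
        with pytest.warns(UserWarning, match="disconnected"):
            gm = gc.global_metrics(gc.WeightedGraph(w))
        assert gm.n_disconnected_pairs == 8
        lm = gc.local_metrics(gc.WeightedGraph(w))
        assert lm.strength[4] == 0.0
        assert lm.clustering_coeff[4] == 0.0
        assert lm.local_efficiency[4] == 0.0

    def test_negative_weights_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.5
        with pytest.raises(ValueError):
            gc.WeightedGraph(w)


class TestOracles:
    def test_path_metrics_match_floyd_warshall(self, rng):
        for _ in range(5):
            g = random_graph(rng)
            d_ref = floyd_warshall_reference(g.weights)
            off = ~np.eye(8, dtype=bool)
            finite = np.isfinite(d_ref) & off
            eglob_ref = np.where(finite, 1.0 / np.where(finite, d_ref, 1), 0.0)[
                off
            ].mean()
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = gc.global_metrics(g)
            assert gm.global_efficiency == pytest.approx(eglob_ref, abs=1e-10)
            if finite.any():
                assert gm.char_path_length == pytest.approx(
                    d_ref[finite].mean(), abs=1e-10
                )

    def test_eigenvector_centrality_matches_dense_eigendecomposition(self, rng):
        for _ in range(5):
            g = random_graph(rng, density=0.9)
            lm = gc.local_metrics(g)
            evals, evecs = np.linalg.eigh(g.weights)
            ref = np.abs(evecs[:, -1])
            assert np.allclose(lm.eigenvector_centrality, ref, atol=1e-8)
            # eigenpair residual
            v = lm.eigenvector_centrality
            lam = v @ g.weights @ v
            assert np.linalg.norm(g.weights @ v - lam * v) < 1e-8

    def test_networkx_agreement_on_clustering_and_strength(self, rng):
        import networkx as nx

        g = random_graph(rng, density=0.9)
        G = nx.from_numpy_array(g.weights)
        lm = gc.local_metrics(g)
        nx_cc = nx.clustering(G, weight="weight")  # Onnela-style in networkx
        # networkx normalizes by the global max weight too
        assert np.allclose(
            lm.clustering_coeff, [nx_cc[i] for i in range(8)], atol=1e-10
        )
        nx_strength = dict(G.degree(weight="weight"))
        assert np.allclose(lm.strength, [nx_strength[i] for i in range(8)])


class TestInvariances:
    def test_weight_scaling_behaviour(self, rng):
        g = random_graph(rng, density=0.9)
        c = 0.37
        gs = gc.WeightedGraph(c * g.weights)
        gm, gms = gc.global_metrics(g), gc.global_metrics(gs)
        lm, lms = gc.local_metrics(g), gc.local_metrics(gs)
        assert gms.global_efficiency == pytest.approx(c * gm.global_efficiency)
        assert gms.char_path_length == pytest.approx(gm.char_path_length / c)
        assert gms.transitivity == pytest.approx(gm.transitivity)
        assert np.allclose(lms.strength, c * lm.strength)
        assert np.allclose(lms.clustering_coeff, lm.clustering_coeff)
        assert np.allclose(
            lms.eigenvector_centrality, lm.eigenvector_centrality, atol=1e-8
        )

    def test_node_permutation_equivariance(self, rng):
        g = random_graph(rng, density=0.9)
        perm = rng.permutation(8)
        gp = gc.WeightedGraph(g.weights[np.ix_(perm, perm)])
        gm, gmp = gc.global_metrics(g), gc.global_metrics(gp)
        assert gmp.global_efficiency == pytest.approx(gm.global_efficiency)
        assert gmp.transitivity == pytest.approx(gm.transitivity)
        lm, lmp = gc.local_metrics(g), gc.local_metrics(gp)
        assert np.allclose(lmp.strength, lm.strength[perm])
        assert np.allclose(lmp.clustering_coeff, lm.clustering_coeff[perm])

    def test_region_means_average_by_label(self):
        vals = np.array([1.0, 3.0, 10.0])
        means = gc.region_means(vals, ["a", "b", "c"], {"a": "L", "b": "L", "c": "R"})
        assert means == {"L": 2.0, "R": 10.0}


class TestTimecourse:
    def _tensor(self, values, conditions):
        return gc.ConnectivityTensor(
            values, WindowGrid(epoch_len_s=2.5),
            np.asarray(conditions, dtype=object), rate=500.0,
        )

    def test_constant_tensor_gives_flat_curves(self):
        w = complete_graph(4).weights * 0.5
        v = np.broadcast_to(w, (4, 19, 4, 4)).copy()
        df = gc.timecourse_global(self._tensor(v, ["FF", "FF", "FU", "FU"]))
        for metric in GLOBAL_METRIC_NAMES:
            vals = df[df["metric"] == metric]["value"]
            assert np.allclose(vals, vals.iloc[0])

    def test_19_points_per_condition_per_metric(self, classification_session):
        df = gc.timecourse_global(classification_session["tensor"])
        counts = df.groupby(["condition", "metric"]).size()
        assert (counts == 19).all()

    def test_single_epoch_condition_flagged_with_nan_ci(self):
        w = complete_graph(3).weights
        v = np.broadcast_to(w, (1, 19, 3, 3)).copy()
        df = gc.timecourse_global(self._tensor(v, ["FF"]))
        assert df["ci_half_width"].isna().all()
        assert (df["n_epochs"] == 1).all()

    def test_empty_tensor_rejected(self):
        v = np.zeros((0, 19, 3, 3))
        with pytest.raises(ValueError):
            gc.timecourse_global(self._tensor(v, []))
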