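"""Layer semantics against explicit double-loop oracle implementations."""

import numpy as np
import pytest
import scipy.sparse as sp

from genegraph.layers import (dense_attention_layer, gcn_layer,
                              kernelized_attention_layer,
                              normalize_adjacency, sage_layer)

from oracles import dense_attention_oracle, gcn_oracle, sage_oracle

RNG = np.random.default_rng(7)


def random_adj(n, p=0.4, seed=0):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return sp.csr_array((upper | upper.T).astype(float))


class TestGCNLayer:
    def test_single_node_identity(self):
        adj = sp.csr_array(np.zeros((1, 1)))
        h = np.array([[2.0, -1.0]])
        out = gcn_layer(h, adj, np.eye(2), normalization="row",
                        self_loops=True, activation=None)
        assert np.allclose(out.data, h)

    def test_path_graph_row_norm_center_is_neighbour_mean(self):
        # A-B-C, all features 1: B's pre-activation = (1 + 1)/deg(B) = 1
        adj = random_adj(3, 0, 0)
        adj = sp.csr_array(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
        h = np.ones((3, 1))
        out = gcn_layer(h, adj, np.eye(1), normalization="row",
                        self_loops=False, activation=None)
        assert np.isclose(out.data[1, 0], 1.0)

    @pytest.mark.parametrize("normalization", ["row", "symmetric"])
    @pytest.mark.parametrize("self_loops", [False, True])
    def test_matches_double_loop_oracle(self, normalization, self_loops):
        adj = random_adj(10, 0.4, seed=3)
        h = RNG.standard_normal((10, 4))
        W = RNG.standard_normal((4, 3))
        out = gcn_layer(h, adj, W, normalization, self_loops)
        ref = gcn_oracle(h, adj, W, normalization, self_loops)
        assert np.abs(out.data - ref).max() < 1e-6

    def test_isolated_node_zero_message(self):
        adj = sp.csr_array(np.zeros((3, 3)))
        out = gcn_layer(np.ones((3, 2)), adj, np.eye(2), "row", False,
                        activation=None)
        assert np.allclose(out.data, 0.0)


class TestSageLayer:
    def test_single_neighbour_aggregate_is_that_neighbour(self):
        adj = sp.csr_array(np.array([[0, 1], [1, 0]], float))
        h = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.vstack([np.zeros((2, 2)), np.eye(2)])  # picks aggregate half
        out = sage_layer(h, adj, W, activation=None)
        assert np.allclose(out.data[0], h[1])

    def test_star_centre_aggregates_leaf_mean(self):
        n = 5
        dense = np.zeros((n, n))
        dense[0, 1:] = dense[1:, 0] = 1
        h = np.vstack([np.zeros(4), np.eye(4)])
        W = np.vstack([np.zeros((4, 4)), np.eye(4)])
        out = sage_layer(h, sp.csr_array(dense), W, activation=None)
        assert np.allclose(out.data[0], np.full(4, 0.25))

    @pytest.mark.parametrize("aggregate", ["mean", "sum"])
    def test_matches_double_loop_oracle(self, aggregate):
        adj = random_adj(12, 0.3, seed=9)
        h = RNG.standard_normal((12, 5))
        W = RNG.standard_normal((10, 4))
        out = sage_layer(h, adj, W, aggregate=aggregate)
        ref = sage_oracle(h, adj, W, aggregate=aggregate)
        assert np.abs(out.data - ref).max() < 1e-6

    def test_isolated_node_zero_aggregate(self):
        adj = sp.csr_array(np.zeros((2, 2)))
        h = np.ones((2, 3))
        W = RNG.standard_normal((6, 2))
        out = sage_layer(h, adj, W, activation=None)
        assert np.allclose(out.data, h @ W[:3])


class TestDenseAttention:
    def test_single_node_returns_its_value_vector(self):
        z = np.array([[1.0, -2.0]])
        wv = RNG.standard_normal((2, 3))
        out = dense_attention_layer(z, np.eye(2), np.eye(2), wv)
        assert np.allclose(out.data, z @ wv)

    def test_identical_keys_give_uniform_attention(self):
        z = RNG.standard_normal((6, 3))
        wk = np.zeros((3, 3))        # all keys identical (zero)
        wv = RNG.standard_normal((3, 2))
        out = dense_attention_layer(z, np.eye(3), wk, wv)
        assert np.allclose(out.data, np.tile((z @ wv).mean(axis=0), (6, 1)))

    def test_attention_rows_normalise_and_match_oracle(self):
        z = RNG.standard_normal((6, 4))
        wq, wk, wv = (RNG.standard_normal((4, 4)) for _ in range(3))
        out = dense_attention_layer(z, wq, wk, wv)
        ref = dense_attention_oracle(z, wq, wk, wv)
        assert np.abs(out.data - ref).max() < 1e-8
        # row normalisation: uniform values must be preserved exactly
        ones = dense_attention_layer(z, wq, wk, np.zeros((4, 1)))
        assert np.allclose(ones.data, 0.0, atol=1e-8)


class TestKernelizedAttention:
    @pytest.mark.parametrize("phi", ["positive_rf", "exp", "elu1"])
    def test_single_node_ratio_cancels(self, phi):
        z = np.array([[0.3, -1.2]])
        wv = RNG.standard_normal((2, 2))
        out = kernelized_attention_layer(z, np.eye(2), np.eye(2), wv, phi=phi,
                                         n_random_features=8, seed=0)
        assert np.allclose(out.data, z @ wv)

    def test_exact_exponential_kernel_matches_dense_in_1d(self):
        # 1-D keys with unit queries: exp(q_u k_v) = e * exp(k_v) and the
        # constant factor cancels in the softmax ratio, so the phi=exp
        # feature map reproduces dense softmax attention exactly
        z = np.column_stack([np.ones(7), RNG.standard_normal((7, 2))])
        wq = np.array([[1.0], [0.0], [0.0]])   # q_u = 1 for every node
        wk = RNG.standard_normal((3, 1))
        wv = RNG.standard_normal((3, 4))
        dense = dense_attention_layer(z, wq, wk, wv)
        kern = kernelized_attention_layer(z, wq, wk, wv, phi="exp")
        assert np.abs(dense.data - kern.data).max() < 1e-6

    def test_random_feature_error_decays_with_m(self):
        z = 0.5 * RNG.standard_normal((8, 4))
        wq, wk, wv = (0.5 * RNG.standard_normal((4, 4)) for _ in range(3))
        dense = dense_attention_layer(z, wq, wk, wv).data
        errors = []
        for m in (64, 512, 4096):
            devs = []
            for seed in range(8):     # average over projections
                kern = kernelized_attention_layer(
                    z, wq, wk, wv, phi="positive_rf", n_random_features=m,
                    seed=seed)
                devs.append(np.abs(kern.data - dense).mean())
            errors.append(np.mean(devs))
        assert errors[0] > errors[1] > errors[2]


def test_normalize_adjacency_modes():
    adj = random_adj(8, 0.5, seed=1)
    row = normalize_adjacency(adj, "row")
    np.testing.assert_allclose(
        np.asarray(row.sum(axis=1)).ravel(),
        np.where(np.asarray(adj.sum(axis=1)).ravel() > 0, 1.0, 0.0))
    sym = normalize_adjacency(adj, "symmetric", self_loops=True)
    assert (abs(sym - sym.T)).max() < 1e-12
    with pytest.raises(ValueError):
        normalize_adjacency(adj, "spectral")
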