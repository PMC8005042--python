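"""Layer operators against hand examples and dense brute-force oracles."""

import numpy as np
import pytest

from multignn.autodiff import Tensor
from multignn.layers import (ARMAParams, BatchNormParams, ContractError,
                             GATParams, GINParams, GraphSignal, LinearParams,
                             SGCParams, arma_layer, batch_norm, gat_attention,
                             gin_update, normalized_adjacency, sgc_propagate)

from conftest import dense_adjacency, random_graph
from oracles import (dense_arma, dense_gat, dense_gin, dense_sgc,
                     dense_sgc_operator)


def identity_mlp(width: int) -> list[LinearParams]:
    eye = lambda: LinearParams(W=Tensor(np.eye(width)), b=None)
    return [eye(), eye()]


def signal_of(x, edges) -> GraphSignal:
    return GraphSignal(x=np.asarray(x, dtype=float),
                       edge_index=np.asarray(edges, dtype=np.int64).reshape(2, -1))


class TestGIN:
    def test_isolated_node_aggregates_zero(self):
        params = GINParams(eps=Tensor(0.0), mlp=identity_mlp(1))
        out = gin_update(signal_of([[1.0]], np.zeros((2, 0))), params)
        np.testing.assert_allclose(out.x, [[1.0]])

    @pytest.mark.parametrize("eps, expected", [
        (0.0, [[3.0], [3.0]]),
        (1.0, [[4.0], [5.0]]),
    ])
    def test_two_connected_nodes_hand_example(self, eps, expected):
        params = GINParams(eps=Tensor(eps), mlp=identity_mlp(1))
        out = gin_update(signal_of([[1.0], [2.0]], [[0, 1], [1, 0]]), params)
        np.testing.assert_allclose(out.x, expected)

    def test_identity_mlp_equals_dense_operator(self):
        """With eps=0 and identity MLP, GIN is (A + I) H (dense oracle)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            h, edges = random_graph(rng, width=3)
            h = np.abs(h)  # keep the inter-layer ReLU inactive
            n = h.shape[0]
            params = GINParams(eps=Tensor(0.0), mlp=identity_mlp(3))
            out = gin_update(signal_of(h, edges), params)
            expected = (dense_adjacency(edges, n) + np.eye(n)) @ h
            np.testing.assert_allclose(out.x, expected, atol=1e-12)

    def test_mlp_width_mismatch_is_contract_error(self):
        params = GINParams(eps=Tensor(0.0), mlp=identity_mlp(4))
        with pytest.raises(ContractError):
            gin_update(signal_of([[1.0]], np.zeros((2, 0))), params)


class TestGAT:
    def make_params(self, rng, d_in, d_out):
        return GATParams.init(rng, d_in, d_out)

    def test_identical_features_attend_uniformly(self):
        rng = np.random.default_rng(3)
        params = self.make_params(rng, 2, 2)
        alpha, edges, _ = gat_attention(
            signal_of([[1.0, 2.0], [1.0, 2.0]], [[0, 1], [1, 0]]), params)
        # each node sees one neighbor plus itself, identical features -> 0.5
        np.testing.assert_allclose(alpha, 0.5 * np.ones(4), atol=1e-12)

    def test_attention_sums_to_one_per_target(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            h, edges = random_graph(rng, width=3)
            params = self.make_params(rng, 3, 5)
            alpha, used_edges, _ = gat_attention(signal_of(h, edges), params)
            sums = np.zeros(h.shape[0])
            np.add.at(sums, used_edges[1], alpha)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_softmax_ratio_identity(self):
        """Two neighbors with raw scores differing by c get ratio exp(c)."""
        rng = np.random.default_rng(5)
        h = rng.normal(size=(3, 2))
        edges = [[1, 2, 0, 0], [0, 0, 1, 2]]  # node 0 has neighbors 1 and 2
        params = self.make_params(rng, 2, 4)
        params.add_self_loops = False
        # make neighborhoods non-empty without self-loops
        edges = [[1, 2, 0, 0, 1, 2], [0, 0, 1, 2, 2, 1]]
        alpha, used_edges, _ = gat_attention(signal_of(h, edges), params)
        wh = h @ params.W.data
        scores = wh @ params.a_dst.data
        raw = lambda i, j: np.where(
            (s := wh[i] @ params.a_dst.data + wh[j] @ params.a_src.data) > 0,
            s, 0.2 * s)
        c = raw(0, 1) - raw(0, 2)
        np.testing.assert_allclose(alpha[0] / alpha[1], np.exp(c), rtol=1e-10)

    def test_empty_neighborhood_without_self_loops_is_contract_error(self):
        rng = np.random.default_rng(6)
        params = self.make_params(rng, 2, 2)
        params.add_self_loops = False
        with pytest.raises(ContractError):
            gat_attention(signal_of([[1.0, 0.0]], np.zeros((2, 0))), params)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            h, edges = random_graph(rng, width=3)
            params = self.make_params(rng, 3, 4)
            _, _, out = gat_attention(signal_of(h, edges), params)
            _, expected = dense_gat(h, dense_adjacency(edges, h.shape[0]),
                                    params.W.data, params.a_src.data,
                                    params.a_dst.data)
            np.testing.assert_allclose(out.x, expected, atol=1e-8)


class TestARMA:
    def test_zero_w_reduces_to_skip_term(self):
        rng = np.random.default_rng(8)
        h = rng.normal(size=(4, 2))
        v = rng.normal(size=(2, 3))
        params = ARMAParams(stacks=[[(LinearParams(W=Tensor(np.zeros((2, 3)))),
                                      LinearParams(W=Tensor(v)))]],
                            activation="identity")
        out = arma_layer(signal_of(h, [[0, 1], [1, 0]]), params)
        np.testing.assert_allclose(out.x, h @ v)

    def test_edgeless_graph_drops_propagation_term(self):
        rng = np.random.default_rng(9)
        h = np.abs(rng.normal(size=(3, 2)))
        w, v = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        params = ARMAParams(stacks=[[(LinearParams(W=Tensor(w)),
                                      LinearParams(W=Tensor(v)))]])
        out = arma_layer(signal_of(h, np.zeros((2, 0))), params)
        np.testing.assert_allclose(out.x, np.maximum(h @ v, 0.0))

    def test_identical_stacks_average_to_single_stack(self):
        rng = np.random.default_rng(10)
        h, edges = random_graph(rng, width=3)
        stack = [(LinearParams(W=Tensor(rng.normal(size=(3, 3)))),
                  LinearParams(W=Tensor(rng.normal(size=(3, 3)))))]
        one = arma_layer(signal_of(h, edges), ARMAParams(stacks=[stack]))
        two = arma_layer(signal_of(h, edges), ARMAParams(stacks=[stack, stack]))
        np.testing.assert_allclose(one.x, two.x, atol=1e-12)

    def test_zero_depth_is_contract_error(self):
        with pytest.raises(ContractError):
            arma_layer(signal_of([[1.0]], np.zeros((2, 0))),
                       ARMAParams(stacks=[]))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            h, edges = random_graph(rng, width=3)
            params = ARMAParams.init(rng, 3, 4, K=2, T=2)
            out = arma_layer(signal_of(h, edges), params)
            stacks_np = [[(w.W.data, v.W.data) for w, v in stack]
                         for stack in params.stacks]
            expected = dense_arma(h, dense_adjacency(edges, h.shape[0]),
                                  stacks_np)
            np.testing.assert_allclose(out.x, expected, atol=1e-8)


class TestSGC:
    def test_edgeless_graph_any_depth_is_linear_map(self):
        h = np.array([[1.0, 2.0], [3.0, 4.0]])
        w = np.array([[1.0], [0.5]])
        params = SGCParams(W=Tensor(w), K=3)
        out = sgc_propagate(signal_of(h, np.zeros((2, 0))), params)
        np.testing.assert_allclose(out.x, h @ w)

    @pytest.mark.parametrize("k", [1, 2])
    def test_two_node_hand_example(self, k):
        """S of a single edge is the rank-one averaging operator [[.5,.5],[.5,.5]]."""
        params = SGCParams(W=Tensor(np.eye(1)), K=k)
        out = sgc_propagate(signal_of([[1.0], [3.0]], [[0, 1], [1, 0]]), params)
        np.testing.assert_allclose(out.x, [[2.0], [2.0]])

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            h, edges = random_graph(rng, width=3)
            params = SGCParams.init(rng, 3, 4, K=int(rng.integers(0, 4)))
            out = sgc_propagate(signal_of(h, edges), params)
            expected = dense_sgc(h, dense_adjacency(edges, h.shape[0]),
                                 params.W.data, params.K)
            np.testing.assert_allclose(out.x, expected, atol=1e-8)

    def test_operator_symmetric_with_bounded_spectrum(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            h, edges = random_graph(rng, width=2)
            s = normalized_adjacency(edges, h.shape[0])
            np.testing.assert_allclose(s, s.T, atol=1e-12)
            np.testing.assert_allclose(s, dense_sgc_operator(
                dense_adjacency(edges, h.shape[0])), atol=1e-12)
            eigenvalues = np.linalg.eigvalsh(s)
            assert np.abs(eigenvalues).max() <= 1.0 + 1e-10


class TestBatchNorm:
    def test_hand_example(self):
        out = batch_norm(np.array([[1.0], [2.0], [3.0]]), np.ones(1),
                         np.zeros(1), eps=1e-12)
        np.testing.assert_allclose(out.ravel(), [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)

    def test_constant_batch_is_zeroed(self):
        out = batch_norm(np.full((3, 1), 5.0), np.ones(1), np.zeros(1))
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_normalization_contract(self):
        rng = np.random.default_rng(14)
        x = rng.normal(2.0, 3.0, size=(64, 5))
        out = batch_norm(x, np.ones(5), np.zeros(5), eps=1e-10)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=0), 1.0, atol=1e-3)

    def test_inverse_affine_recovers_input(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(32, 4))
        mu, sd = x.mean(axis=0), x.std(axis=0)
        out = batch_norm(x, gamma=sd, beta=mu, eps=1e-14)
        np.testing.assert_allclose(out, x, atol=1e-6)


class TestPermutationEquivariance:
    @pytest.mark.parametrize("layer_name", ["gin", "gat", "arma", "sgc"])
    def test_node_relabeling_permutes_outputs(self, layer_name):
        rng = np.random.default_rng(16)
        for _ in range(10):
            h, edges = random_graph(rng, width=3)
            n = h.shape[0]
            params = {
                "gin": lambda: GINParams.init(rng, 3, 4),
                "gat": lambda: GATParams.init(rng, 3, 4),
                "arma": lambda: ARMAParams.init(rng, 3, 4),
                "sgc": lambda: SGCParams.init(rng, 3, 4),
            }[layer_name]()

            def apply(sig):
                if layer_name == "gin":
                    return gin_update(sig, params).x
                if layer_name == "gat":
                    return gat_attention(sig, params)[2].x
                if layer_name == "arma":
                    return arma_layer(sig, params).x
                return sgc_propagate(sig, params).x

            perm = rng.permutation(n)
            inverse = np.argsort(perm)
            permuted = GraphSignal(x=h[perm],
                                   edge_index=inverse[edges] if edges.size
                                   else edges)
            base = apply(GraphSignal(x=h, edge_index=edges))
            shuffled = apply(permuted)
            tol = 1e-6 if layer_name == "gat" else 1e-12
            np.testing.assert_allclose(shuffled, base[perm], atol=tol)
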