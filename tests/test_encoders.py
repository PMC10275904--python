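"""Both encoders against brute-force oracles and hand computations."""

import numpy as np
import pytest

from ddacl.autodiff import Tensor
from ddacl.data_io import AssociationMatrix, SimilarityMatrix
from ddacl.encoders import (
    AttentionEncoderParams,
    DdaEncoderParams,
    attention_coefficients,
    ba_aggregate,
    dda_encode,
    ga_aggregate,
    global_scores,
    pair_scores,
    similarity_encode,
)
from ddacl.views import build_knn_graph, extended_neighborhoods


def _assoc(values):
    values = np.asarray(values)
    n, m = values.shape
    return AssociationMatrix([f"r{i}" for i in range(n)],
                             [f"d{j}" for j in range(m)], values)


def _linear_params(t, beta=0.5):
    return DdaEncoderParams(w_g=Tensor(np.eye(t)), w_b=Tensor(np.eye(t)),
                            beta=beta, activation="linear")


def _random_view_and_features(rng, n=6, m=4, t=5):
    values = rng.integers(0, 2, size=(n, m))
    view = extended_neighborhoods(_assoc(values))
    e = rng.normal(size=(n + m, t))
    return view, e


# --------------------------------------------------------------- GA oracle
def ga_oracle(e, view, w_g):
    """Naive double loop over extended neighbourhoods (linear activation)."""
    out = np.zeros_like(e @ w_g)
    d = view.d_hat
    for v, nbrs in enumerate(view.extended_neighbors):
        for i in nbrs:
            out[v] += (w_g.T @ e[i]) / np.sqrt(d[v] * d[i])
    return out


def ba_oracle(e, view, w_b):
    """Explicit O(d̂²) pairwise loop (linear activation)."""
    t = e.shape[1]
    out = np.zeros((len(view.d_hat), t))
    for v, nbrs in enumerate(view.extended_neighbors):
        pairs = [(i, j) for a, i in enumerate(nbrs) for j in nbrs[a + 1:]]
        if not pairs:
            continue
        acc = np.zeros(t)
        for i, j in pairs:
            acc += (e[i] @ w_b) * (e[j] @ w_b)
        out[v] = acc / len(pairs)
    return out


class TestGaAggregate:
    def test_isolated_node_identity(self):
        view = extended_neighborhoods(_assoc([[0, 0]]))
        e = np.arange(9, dtype=float).reshape(3, 3)
        out = ga_aggregate(Tensor(e), view, _linear_params(3))
        np.testing.assert_allclose(out.data[0], e[0])

    def test_star_averages_embeddings(self):
        view = extended_neighborhoods(_assoc([[1]]))  # drug-disease pair, d̂=2 each
        e = np.array([[2.0, 4.0], [6.0, 8.0]])
        out = ga_aggregate(Tensor(e), view, _linear_params(2))
        np.testing.assert_allclose(out.data[0], (e[0] + e[1]) / 2)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        view, e = _random_view_and_features(rng)
        w_g = rng.normal(size=(5, 5))
        params = DdaEncoderParams(w_g=Tensor(w_g), w_b=Tensor(np.eye(5)),
                                  beta=1.0, activation="linear")
        out = ga_aggregate(Tensor(e), view, params)
        np.testing.assert_allclose(out.data, ga_oracle(e, view, w_g), atol=1e-6)

    def test_product_normalization_variant(self):
        view = extended_neighborhoods(_assoc([[1]]))
        e = np.array([[2.0, 4.0], [6.0, 8.0]])
        params = _linear_params(2)
        params.norm = "product"
        out = ga_aggregate(Tensor(e), view, params)
        np.testing.assert_allclose(out.data[0], (e[0] + e[1]) / 4)


class TestBaAggregate:
    def test_single_pair_is_elementwise_product(self):
        view = extended_neighborhoods(_assoc([[1]]))
        e = np.array([[2.0, 3.0], [4.0, 5.0]])
        out = ba_aggregate(Tensor(e), view, _linear_params(2))
        np.testing.assert_allclose(out.data[0], e[0] * e[1])

    def test_all_ones_neighborhood_of_three(self):
        view = extended_neighborhoods(_assoc([[1, 1]]))
        e = np.ones((3, 4))
        out = ba_aggregate(Tensor(e), view, _linear_params(4))
        np.testing.assert_allclose(out.data[0], np.ones(4))

    def test_degree_one_gives_zero_preactivation(self):
        view = extended_neighborhoods(_assoc([[0, 0]]))
        e = np.random.default_rng(0).normal(size=(3, 2))
        out = ba_aggregate(Tensor(e), view, _linear_params(2))
        np.testing.assert_array_equal(out.data[0], 0.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_fast_form_equals_pairwise_loop(self, seed):
        rng = np.random.default_rng(seed)
        view, e = _random_view_and_features(rng)
        w_b = rng.normal(size=(5, 5))
        params = DdaEncoderParams(w_g=Tensor(np.eye(5)), w_b=Tensor(w_b),
                                  beta=0.0, activation="linear")
        out = ba_aggregate(Tensor(e), view, params)
        np.testing.assert_allclose(out.data, ba_oracle(e, view, w_b), atol=1e-6)


class TestDdaEncode:
    @pytest.mark.parametrize("beta", [0.0, 1.0])
    def test_endpoints_reduce_to_single_aggregator(self, rng, beta):
        view, e = _random_view_and_features(rng)
        params = DdaEncoderParams(w_g=Tensor(rng.normal(size=(5, 5))),
                                  w_b=Tensor(rng.normal(size=(5, 5))), beta=beta)
        out = dda_encode(Tensor(e), view, params)
        single = (ga_aggregate if beta == 1.0 else ba_aggregate)(Tensor(e), view, params)
        np.testing.assert_array_equal(out.data, single.data)

    def test_convex_combination_componentwise(self, rng):
        view, e = _random_view_and_features(rng)
        params = DdaEncoderParams(w_g=Tensor(rng.normal(size=(5, 5))),
                                  w_b=Tensor(rng.normal(size=(5, 5))),
                                  beta=0.6, activation="linear")
        out = dda_encode(Tensor(e), view, params)
        ga = ga_aggregate(Tensor(e), view, params)
        ba = ba_aggregate(Tensor(e), view, params)
        np.testing.assert_allclose(out.data, 0.6 * ga.data + 0.4 * ba.data, atol=1e-12)

    def test_linear_in_beta(self, rng):
        view, e = _random_view_and_features(rng)
        outs = {}
        for beta in (0.2, 0.5, 0.8):
            params = DdaEncoderParams(w_g=Tensor(np.eye(5)), w_b=Tensor(np.eye(5)),
                                      beta=beta, activation="linear")
            outs[beta] = dda_encode(Tensor(e), view, params).data
        np.testing.assert_allclose(outs[0.5], 0.5 * (outs[0.2] + outs[0.8]), atol=1e-10)


def _att_params(t, rng=None, zero=False):
    if zero:
        mk = lambda *s: Tensor(np.zeros(s))
    else:
        mk = lambda *s: Tensor(rng.normal(size=s))
    return AttentionEncoderParams(w1=mk(t, t), w2=mk(t, t), w3=mk(t, t),
                                  att1=mk(t, 1), att2=mk(2 * t, 1))


def _knn(rng, n=5, k=2):
    v = rng.random((n, n))
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 1.0)
    return build_knn_graph(SimilarityMatrix([f"n{i}" for i in range(n)], v), k)


class TestGlobalScores:
    def test_single_node_mean_is_itself(self):
        params = AttentionEncoderParams(
            w1=Tensor(np.eye(2)), w2=Tensor(np.eye(2)), w3=Tensor(np.eye(2)),
            att1=Tensor(np.ones((2, 1))), att2=Tensor(np.ones((4, 1))))
        e = np.array([[3.0, 2.0]])
        out = global_scores(Tensor(e), params)
        np.testing.assert_allclose(out.data, [[13.0]])  # 3*3 + 2*2

    def test_identical_nodes_get_equal_scores(self, rng):
        params = _att_params(3, rng)
        e = np.tile(rng.normal(size=(1, 3)), (5, 1))
        out = global_scores(Tensor(e), params).data
        assert np.ptp(out) < 1e-12

    def test_two_node_hand_computation(self):
        w1 = np.array([[1.0, 0.0], [1.0, 1.0]])
        att1 = np.array([[2.0], [-1.0]])
        params = AttentionEncoderParams(w1=Tensor(w1), w2=Tensor(np.eye(2)),
                                        w3=Tensor(np.eye(2)), att1=Tensor(att1),
                                        att2=Tensor(np.zeros((4, 1))))
        e = np.array([[1.0, 2.0], [3.0, 0.0]])
        e_bar = e.mean(axis=0)  # [2, 1]
        expected = []
        for row in e:
            z = (row @ w1) * e_bar
            s = float(z @ att1[:, 0])
            expected.append(s if s > 0 else 0.2 * s)
        out = global_scores(Tensor(e), params)
        np.testing.assert_allclose(out.data[:, 0], expected, atol=1e-8)


class TestPairScores:
    def test_zero_weights_give_zero_scores(self, rng):
        knn = _knn(rng)
        out = pair_scores(Tensor(rng.normal(size=(5, 3))), knn, _att_params(3, zero=True))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_asymmetric_in_edge_direction(self, rng):
        params = _att_params(2, rng)
        e = rng.normal(size=(3, 2))
        z = e @ params.w2.data
        s_01 = np.concatenate([z[0], z[1]]) @ params.att2.data[:, 0]
        s_10 = np.concatenate([z[1], z[0]]) @ params.att2.data[:, 0]
        assert not np.isclose(s_01, s_10)

    def test_three_node_hand_computation(self, rng):
        knn = _knn(rng, n=3, k=1)
        params = _att_params(2, rng)
        e = rng.normal(size=(3, 2))
        out = pair_scores(Tensor(e), knn, params).data
        z = e @ params.w2.data
        src, dst = knn.edges
        for row, (i, j) in enumerate(zip(src, dst)):
            s = np.concatenate([z[i], z[j]]) @ params.att2.data[:, 0]
            expected = s if s > 0 else 0.2 * s
            np.testing.assert_allclose(out[row, 0], expected, atol=1e-8)


class TestAttentionCoefficients:
    def test_uniform_logits_give_uniform_weights(self, rng):
        knn = _knn(rng, n=5, k=4)
        eps = Tensor(np.zeros((5, 1)))
        zeta = Tensor(np.zeros((20, 1)))
        delta = attention_coefficients(eps, zeta, knn)
        np.testing.assert_allclose(delta.data, 0.25)

    def test_dominant_logit_saturates(self, rng):
        knn = _knn(rng, n=4, k=3)
        src, dst = knn.edges
        zeta = np.zeros((len(src), 1))
        zeta[0, 0] = 100.0
        delta = attention_coefficients(Tensor(np.zeros((4, 1))), Tensor(zeta), knn)
        assert delta.data[0, 0] > 0.999

    @pytest.mark.parametrize("seed", range(25))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        knn = _knn(rng, n=6, k=3)
        src, _ = knn.edges
        eps = Tensor(rng.normal(size=(6, 1)) * 5)
        zeta = Tensor(rng.normal(size=(len(src), 1)) * 5)
        delta = attention_coefficients(eps, zeta, knn).data[:, 0]
        sums = np.zeros(6)
        np.add.at(sums, src, delta)
        np.testing.assert_allclose(sums, 1.0, atol=1e-7)


class TestSimilarityEncode:
    def test_single_neighbour_degenerate_softmax(self, rng):
        knn = _knn(rng, n=3, k=1)
        params = _att_params(2, rng)
        params.activation = "linear"
        h = rng.normal(size=(3, 2))
        eps = global_scores(Tensor(h), params)
        zeta = pair_scores(Tensor(h), knn, params)
        delta = attention_coefficients(eps, zeta, knn)
        out = similarity_encode(Tensor(h), delta, knn, params)
        src, dst = knn.edges
        for i, j in zip(src, dst):
            np.testing.assert_allclose(out.data[i], h[j] @ params.w3.data, atol=1e-10)

    def test_uniform_weights_average_neighbours(self, rng):
        knn = _knn(rng, n=4, k=2)
        params = _att_params(3, zero=True)
        params.w3 = Tensor(np.eye(3))
        params.activation = "linear"
        h = rng.normal(size=(4, 3))
        delta = attention_coefficients(Tensor(np.zeros((4, 1))),
                                       Tensor(np.zeros((8, 1))), knn)
        out = similarity_encode(Tensor(h), delta, knn, params)
        for i in range(4):
            nbrs = np.flatnonzero(knn.adjacency[i])
            np.testing.assert_allclose(out.data[i], h[nbrs].mean(axis=0), atol=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_weighted_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        knn = _knn(rng, n=5, k=2)
        params = _att_params(3, rng)
        params.activation = "linear"
        e = rng.normal(size=(5, 3))
        h = rng.normal(size=(5, 3))
        eps = global_scores(Tensor(e), params)
        zeta = pair_scores(Tensor(e), knn, params)
        delta = attention_coefficients(eps, zeta, knn)
        out = similarity_encode(Tensor(h), delta, knn, params)
        src, dst = knn.edges
        expected = np.zeros((5, 3))
        for row, (i, j) in enumerate(zip(src, dst)):
            expected[i] += delta.data[row, 0] * (h[j] @ params.w3.data)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_aggregate_e_variant(self, rng):
        knn = _knn(rng, n=4, k=2)
        params = _att_params(2, rng)
        h = rng.normal(size=(4, 2))
        e = rng.normal(size=(4, 2))
        delta = attention_coefficients(Tensor(np.zeros((4, 1))),
                                       Tensor(np.zeros((8, 1))), knn)
        out_h = similarity_encode(Tensor(h), delta, knn, params)
        out_e = similarity_encode(Tensor(h), delta, knn, params, aggregate="e", e=Tensor(e))
        assert not np.allclose(out_h.data, out_e.data)


def test_encoder_outputs_finite_for_bounded_inputs(rng):
    view, e = _random_view_and_features(rng, n=8, m=6, t=4)
    e = np.clip(e * 5, -10, 10)
    params = DdaEncoderParams.init(4, beta=0.6, rng=rng)
    h = dda_encode(Tensor(e), view, params)
    assert np.isfinite(h.data).all()
    knn = _knn(rng, n=8, k=3)
    att = AttentionEncoderParams.init(4, rng)
    eps = global_scores(Tensor(e[:8]), att)
    zeta = pair_scores(Tensor(e[:8]), knn, att)
    delta = attention_coefficients(eps, zeta, knn)
    q = similarity_encode(Tensor(e[:8]), delta, knn, att)
    assert np.isfinite(q.data).all()
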