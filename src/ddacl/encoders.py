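"""The two graph encoders.

DDA-view encoder: a convex β-mix of a GCN-style weighted-sum (GA) aggregator
and a bilinear (BA) aggregator that sums element-wise products over all
pairs of extended neighbours, both over the bipartite association graph.

Similarity-view encoder: a global-aware attention layer on the kNN graph
whose logits add a node-vs-graph-average score ϵ and a pairwise score ζ;
the attention aggregates the DDA-view embeddings h of the kNN neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_sum, xavier_uniform
from .views import BipartiteView, KnnGraph

__all__ = [
    "DdaEncoderParams",
    "AttentionEncoderParams",
    "EncoderOutputs",
    "ga_matrix",
    "ga_aggregate",
    "ba_aggregate",
    "dda_encode",
    "global_scores",
    "pair_scores",
    "attention_coefficients",
    "similarity_encode",
]


def _activation(name: str):
    if name == "relu":
        return lambda t: t.relu()
    if name == "linear":
        return lambda t: t
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class DdaEncoderParams:
    """Shared weights of the bipartite-view encoder (one graph, shared W's)."""

    w_g: Tensor
    w_b: Tensor
    beta: float
    activation: str = "relu"
    norm: str = "symmetric"  # a_vi = 1/sqrt(d̂_v d̂_i); "product" gives 1/(d̂_v d̂_i)

    @classmethod
    def init(cls, dim: int, beta: float, rng: np.random.Generator, **kw) -> "DdaEncoderParams":
        return cls(
            w_g=Tensor(xavier_uniform(rng, dim, dim), requires_grad=True),
            w_b=Tensor(xavier_uniform(rng, dim, dim), requires_grad=True),
            beta=beta,
            **kw,
        )

    @property
    def params(self) -> list[Tensor]:
        return [self.w_g, self.w_b]


@dataclass
class AttentionEncoderParams:
    """Per-node-type weights of the similarity-view attention encoder."""

    w1: Tensor
    w2: Tensor
    w3: Tensor
    att1: Tensor  # (t, 1) scorer over W1 e ⊙ ē
    att2: Tensor  # (2t, 1) scorer over [W2 e_i ‖ W2 e_j]
    leaky_slope: float = 0.2
    activation: str = "relu"

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator, **kw) -> "AttentionEncoderParams":
        return cls(
            w1=Tensor(xavier_uniform(rng, dim, dim), requires_grad=True),
            w2=Tensor(xavier_uniform(rng, dim, dim), requires_grad=True),
            w3=Tensor(xavier_uniform(rng, dim, dim), requires_grad=True),
            att1=Tensor(xavier_uniform(rng, dim, 1), requires_grad=True),
            att2=Tensor(xavier_uniform(rng, 2 * dim, 1), requires_grad=True),
            **kw,
        )

    @property
    def params(self) -> list[Tensor]:
        return [self.w1, self.w2, self.w3, self.att1, self.att2]


@dataclass
class EncoderOutputs:
    """Per-node embeddings from both encoders, split by node type."""

    h_drug: Tensor
    h_disease: Tensor
    q_drug: Tensor
    q_disease: Tensor
    e_drug: Tensor = field(default=None)
    e_disease: Tensor = field(default=None)


# --------------------------------------------------------------- DDA encoder

def ga_matrix(view: BipartiteView, norm: str = "symmetric") -> np.ndarray:
    """Dense aggregation matrix S with S[v, i] = a_vi over N̂ membership."""
    adj = view.adjacency_with_self()
    d = view.d_hat.astype(np.float64)
    if norm == "symmetric":
        scale = 1.0 / np.sqrt(np.outer(d, d))
    elif norm == "product":
        scale = 1.0 / np.outer(d, d)
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    return adj * scale


def ga_aggregate(e: Tensor, view: BipartiteView, params: DdaEncoderParams) -> Tensor:
    """h_v = σ( Σ_{i∈N̂(v)} a_vi W_g e_i ) for every node at once."""
    s = Tensor(ga_matrix(view, params.norm))
    act = _activation(params.activation)
    return act(s @ (e @ params.w_g))


def ba_aggregate(e: Tensor, view: BipartiteView, params: DdaEncoderParams) -> Tensor:
    """Bilinear aggregation over all neighbour pairs inside N̂(v).

    Uses the algebraic identity
        Σ_{i<j} z_i⊙z_j = ½[(Σ z_i)⊙(Σ z_i) − Σ z_i⊙z_i],  z = W_b e,
    normalized by the pair count b_v = ½ d̂_v (d̂_v − 1); nodes with d̂_v = 1
    have no pairs and get a zero pre-activation.
    """
    adj = Tensor(view.adjacency_with_self())
    d = view.d_hat.astype(np.float64)
    b_v = 0.5 * d * (d - 1.0)
    inv_b = np.where(b_v > 0, 1.0 / np.where(b_v > 0, b_v, 1.0), 0.0)
    z = e @ params.w_b
    s1 = adj @ z
    s2 = adj @ (z * z)
    pre = (s1 * s1 - s2) * Tensor(0.5 * inv_b[:, None])
    return _activation(params.activation)(pre)


def dda_encode(e: Tensor, view: BipartiteView, params: DdaEncoderParams) -> Tensor:
    """β-mix of the GA and BA aggregators."""
    if not 0.0 <= params.beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    if params.beta == 1.0:
        return ga_aggregate(e, view, params)
    if params.beta == 0.0:
        return ba_aggregate(e, view, params)
    return (
        ga_aggregate(e, view, params) * params.beta
        + ba_aggregate(e, view, params) * (1.0 - params.beta)
    )


# -------------------------------------------------------- similarity encoder

def global_scores(e: Tensor, params: AttentionEncoderParams) -> Tensor:
    """ϵ_i = LeakyReLU(att1ᵀ (W1 e_i ⊙ ē)), ē the mean embedding. Shape (n, 1)."""
    e_bar = e.mean(axis=0, keepdims=True)
    return ((e @ params.w1) * e_bar @ params.att1).leaky_relu(params.leaky_slope)


def pair_scores(e: Tensor, knn: KnnGraph, params: AttentionEncoderParams) -> Tensor:
    """ζ_ij = LeakyReLU(att2ᵀ [W2 e_i ‖ W2 e_j]) per directed kNN edge. Shape (E, 1)."""
    src, dst = knn.edges
    z = e @ params.w2
    cat = concat([gather_rows(z, src), gather_rows(z, dst)], axis=1)
    return (cat @ params.att2).leaky_relu(params.leaky_slope)


def attention_coefficients(eps: Tensor, zeta: Tensor, knn: KnnGraph) -> Tensor:
    """δ_ij = softmax over j∈N(i) of (ϵ_j + ζ_ij), per-row max-subtracted. Shape (E, 1)."""
    src, dst = knn.edges
    n = knn.adjacency.shape[0]
    if np.setdiff1d(np.arange(n), src).size:
        raise ValueError("every node needs at least one kNN neighbour")
    logits = gather_rows(eps, dst) + zeta
    row_max = np.full((n, 1), -np.inf)
    np.maximum.at(row_max, src, logits.data)
    ex = (logits - row_max[src]).exp()
    denom = segment_sum(ex, src, n)
    return ex / gather_rows(denom, src)


def similarity_encode(h: Tensor, delta: Tensor, knn: KnnGraph,
                      params: AttentionEncoderParams, aggregate: str = "h",
                      e: Tensor | None = None) -> Tensor:
    """q_i = σ( Σ_{j∈N(i)} δ_ij W3 h_j ).

    The aggregation runs over the DDA-view embeddings h of the similarity-view
    neighbours; ``aggregate="e"`` switches to the raw features (ablation).
    """
    src, dst = knn.edges
    n = knn.adjacency.shape[0]
    source = h if aggregate == "h" else e
    if source is None:
        raise ValueError("aggregate='e' requires the feature tensor e")
    msgs = gather_rows(source @ params.w3, dst) * delta
    return _activation(params.activation)(segment_sum(msgs, src, n))
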