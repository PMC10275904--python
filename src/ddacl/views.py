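"""Contrast-view construction.

Three graphs are contrasted during training: the drug-disease association
(DDA) bipartite view and two top-K nearest-neighbour similarity views, one
per node type. Nodes carry global indices: drugs 0..N-1, diseases N..N+M-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix, SimilarityMatrix

__all__ = ["KnnGraph", "BipartiteView", "build_knn_graph", "extended_neighborhoods"]


@dataclass
class KnnGraph:
    """Row-wise top-k neighbour graph derived from a similarity matrix."""

    ids: list[str]
    adjacency: np.ndarray  # square {0,1}, zero diagonal
    k: int

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(src, dst) arrays for all directed edges i -> j with adj[i, j] = 1."""
        src, dst = np.nonzero(self.adjacency)
        return src, dst


@dataclass
class BipartiteView:
    """The DDA bipartite graph with self-inclusive extended neighbourhoods.

    ``extended_neighbors[v]`` lists global node ids of N̂(v) = {v} ∪ bipartite
    neighbours; ``d_hat[v] = |N̂(v)|``.
    """

    assoc: AssociationMatrix
    extended_neighbors: list[np.ndarray] = field(repr=False)
    d_hat: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.assoc.n_drugs + self.assoc.n_diseases

    def adjacency_with_self(self) -> np.ndarray:
        """Dense (N+M) x (N+M) binary matrix of N̂ membership (self-loops set)."""
        n = self.n_nodes
        out = np.zeros((n, n))
        for v, nbrs in enumerate(self.extended_neighbors):
            out[v, nbrs] = 1.0
        return out


def build_knn_graph(sim: SimilarityMatrix, k: int, symmetrize: bool = False) -> KnnGraph:
    """Connect each node to its k most similar other nodes.

    Ties are broken toward the smaller index; the node itself is never a
    candidate. The result is directed (row-wise); ``symmetrize=True`` takes
    the union of each edge and its reverse.
    """
    n = sim.n
    if n < 2:
        raise ValueError("kNN graph requires at least 2 nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n - 1:
        warnings.warn(f"k={k} exceeds n-1={n - 1}; clamping", stacklevel=2)
        k = n - 1
    scores = sim.values.astype(np.float64).copy()
    np.fill_diagonal(scores, -np.inf)
    # stable argsort on -scores: ties resolve to the smaller index
    order = np.argsort(-scores, axis=1, kind="stable")
    adj = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    adj[rows, order[:, :k].ravel()] = 1.0
    if symmetrize:
        adj = np.maximum(adj, adj.T)
    return KnnGraph(ids=list(sim.ids), adjacency=adj, k=k)


def extended_neighborhoods(assoc: AssociationMatrix) -> BipartiteView:
    """Build N̂(v) = {v} ∪ neighbours for every drug and disease node."""
    n, m = assoc.n_drugs, assoc.n_diseases
    a = assoc.values
    neighbors: list[np.ndarray] = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i]) + n  # diseases carry offset N
        neighbors.append(np.concatenate(([i], nbrs)))
    for j in range(m):
        nbrs = np.flatnonzero(a[:, j])
        neighbors.append(np.concatenate(([n + j], nbrs)))
    d_hat = np.array([len(x) for x in neighbors], dtype=np.int64)
    return BipartiteView(assoc=assoc, extended_neighbors=neighbors, d_hat=d_hat)
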