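"""Initial node features: random walk with restart plus a learned projection.

Each node's feature vector is its RWR steady-state profile on that node
type's similarity view — the column of α(I − (1−α)P)⁻¹ seeded at the node —
passed through a small trainable perceptron that maps it to t dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, xavier_uniform

__all__ = [
    "RwrProfile",
    "NodeFeatures",
    "FeatureProjector",
    "column_normalize",
    "rwr",
    "rwr_closed_form",
]


@dataclass
class RwrProfile:
    restart_prob: float
    transition: np.ndarray      # column-stochastic P
    profiles: np.ndarray        # column i = steady state seeded at node i
    n_iterations: int


@dataclass
class NodeFeatures:
    embeddings: Tensor  # n x t
    dim: int


def column_normalize(adjacency: np.ndarray) -> np.ndarray:
    """Divide each column by its sum; all-zero columns become self-absorbing."""
    adjacency = np.asarray(adjacency, dtype=np.float64)
    if (adjacency < 0).any():
        raise ValueError("adjacency must be non-negative")
    sums = adjacency.sum(axis=0)
    zero_cols = np.flatnonzero(sums == 0)
    p = adjacency.copy()
    if zero_cols.size:
        warnings.warn(
            f"{zero_cols.size} all-zero column(s) made self-absorbing", stacklevel=2
        )
        p[zero_cols, zero_cols] = 1.0
        sums = p.sum(axis=0)
    return p / sums


def rwr(transition: np.ndarray, restart_prob: float, tol: float = 1e-6,
        max_iter: int = 1000) -> RwrProfile:
    """Iterate x(l+1) = (1-α) P x(l) + α x(0) to the steady state, all seeds at once.

    Started from the identity (one-hot seed per column); stops when the
    largest entry change falls below ``tol``.
    """
    if not 0 < restart_prob <= 1:
        raise ValueError("restart probability must be in (0, 1]")
    p = np.asarray(transition, dtype=np.float64)
    n = p.shape[0]
    col_sums = p.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-8):
        raise ValueError("transition matrix must be column-stochastic")
    x0 = np.eye(n)
    x = x0.copy()
    for it in range(1, max_iter + 1):
        x_next = (1.0 - restart_prob) * (p @ x) + restart_prob * x0
        delta = np.abs(x_next - x).max()
        x = x_next
        if delta < tol:
            return RwrProfile(restart_prob, p, x, it)
    raise RuntimeError(
        f"RWR did not converge in {max_iter} iterations (residual {delta:.3g})"
    )


def rwr_closed_form(transition: np.ndarray, restart_prob: float) -> np.ndarray:
    """Closed-form steady state α(I − (1−α)P)⁻¹ for every one-hot seed."""
    p = np.asarray(transition, dtype=np.float64)
    n = p.shape[0]
    return restart_prob * np.linalg.solve(np.eye(n) - (1.0 - restart_prob) * p, np.eye(n))


class FeatureProjector:
    """One-hidden-layer perceptron mapping RWR profiles to t-dim embeddings.

    Hidden width equals the output width t; ReLU on the hidden layer, linear
    output. Drugs and diseases each get their own projector since their
    profile dimensions (N vs M) differ.
    """

    def __init__(self, in_dim: int, dim: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.dim = dim
        self.w1 = Tensor(xavier_uniform(rng, in_dim, dim), requires_grad=True)
        self.b1 = Tensor(np.zeros(dim), requires_grad=True)
        self.w2 = Tensor(xavier_uniform(rng, dim, dim), requires_grad=True)
        self.b2 = Tensor(np.zeros(dim), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, profiles: np.ndarray | Tensor) -> Tensor:
        x = profiles if isinstance(profiles, Tensor) else Tensor(profiles)
        if x.shape[1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} input features, got {x.shape[1]}")
        hidden = (x @ self.w1 + self.b1).relu()
        return hidden @ self.w2 + self.b2


def project_features(profiles: np.ndarray, projector: FeatureProjector) -> NodeFeatures:
    """Project the rows of a profile matrix (one row per node) to t dims."""
    emb = projector(profiles)
    return NodeFeatures(embeddings=emb, dim=projector.dim)
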