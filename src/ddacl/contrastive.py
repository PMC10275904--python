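"""Cross-view pseudo-label mining and the NT-Xent co-contrastive objective.

Pseudo-labels for an anchor node come from its *similarity-view* embedding q:
a softmax over inner products with all opposite-type q's scores every
candidate, the top-k become positives, and hard negatives are drawn
uniformly from the top half of the ranking minus the positives. The NT-Xent
loss is then taken over the *DDA-view* embeddings h — labels mined in one
view supervise the other, symmetrically for drugs and diseases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, gather_rows
from .encoders import EncoderOutputs

__all__ = [
    "ContrastiveBatch",
    "ContrastiveConfig",
    "cross_view_scores",
    "sample_positives",
    "sample_hard_negatives",
    "ntxent_loss",
    "co_contrastive_loss",
]


@dataclass
class ContrastiveBatch:
    """Per-anchor positive and hard-negative index sets over the opposite type."""

    anchor_ids: np.ndarray
    positives: list[np.ndarray]
    negatives: list[np.ndarray]
    k_pos: int
    k_neg: int

    def __post_init__(self) -> None:
        for pos, neg in zip(self.positives, self.negatives):
            if len(pos) != self.k_pos or len(neg) != self.k_neg:
                raise ValueError("positive/negative set sizes do not match k_pos/k_neg")
            if np.intersect1d(pos, neg).size:
                raise ValueError("positives and negatives overlap")


@dataclass
class ContrastiveConfig:
    temperature: float = 0.1
    k_pos: int = 5
    k_neg: int = 5
    hard_pool_fraction: float = 0.5
    batch_size: int = 64
    per_positive: bool = False  # InfoNCE mean-over-positives variant

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.hard_pool_fraction <= 1:
            raise ValueError("hard_pool_fraction must be in (0, 1]")
        if self.k_pos < 1 or self.k_neg < 1:
            raise ValueError("k_pos and k_neg must be >= 1")


def cross_view_scores(q_anchor: np.ndarray, q_opposite: np.ndarray) -> np.ndarray:
    """softmax(Q_opposite · q_anchor): confidence of each opposite-type node."""
    logits = np.asarray(q_opposite, dtype=np.float64) @ np.asarray(q_anchor, dtype=np.float64)
    logits -= logits.max()
    ex = np.exp(logits)
    return ex / ex.sum()


def sample_positives(score: np.ndarray, k_pos: int) -> np.ndarray:
    """Indices of the k_pos highest scores; ties go to the smaller index."""
    score = np.asarray(score)
    if k_pos > score.size:
        raise ValueError(f"k_pos={k_pos} exceeds {score.size} candidates")
    return np.argsort(-score, kind="stable")[:k_pos]


def sample_hard_negatives(score: np.ndarray, positives: np.ndarray, k_neg: int,
                          hard_pool_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw of k_neg indices from the top-ranked pool minus positives."""
    score = np.asarray(score)
    pool_size = math.ceil(hard_pool_fraction * score.size)
    ranked = np.argsort(-score, kind="stable")[:pool_size]
    pool = ranked[~np.isin(ranked, positives)]
    if pool.size < k_neg:
        raise ValueError(
            f"hard-negative pool has {pool.size} candidates < k_neg={k_neg}; "
            "reduce k_neg or enlarge hard_pool_fraction"
        )
    return rng.choice(pool, size=k_neg, replace=False)


def _cosine_matrix(h_a: Tensor, h_b: Tensor) -> Tensor:
    for t in (h_a, h_b):
        norms = np.sqrt((t.data ** 2).sum(axis=1))
        if (norms == 0).any():
            raise ValueError("zero-norm embedding: cosine similarity undefined")
    na = h_a / (h_a * h_a).sum(axis=1, keepdims=True).sqrt()
    nb = h_b / (h_b * h_b).sum(axis=1, keepdims=True).sqrt()
    return na @ nb.T


def ntxent_loss(h_anchor: Tensor, h_opposite: Tensor, batch: ContrastiveBatch,
                temperature: float, per_positive: bool = False) -> Tensor:
    """NT-Xent with all positives summed inside one log (per-anchor):

        L = −log [ Σ_{j∈S+} exp(cos(h_a, h_j)/τ) / Σ_{k∈S+∪S−} exp(cos/τ) ]

    averaged over anchors. ``per_positive=True`` switches to the InfoNCE
    variant that averages one log-term per positive.
    """
    b = len(batch.anchor_ids)
    n_opp = h_opposite.shape[0]
    sims = _cosine_matrix(gather_rows(h_anchor, batch.anchor_ids), h_opposite)
    logits = sims / temperature
    pos_mask = np.zeros((b, n_opp))
    all_mask = np.zeros((b, n_opp))
    for row, (pos, neg) in enumerate(zip(batch.positives, batch.negatives)):
        pos_mask[row, pos] = 1.0
        all_mask[row, pos] = 1.0
        all_mask[row, neg] = 1.0
    # shift by the per-row candidate max (constant shift: softmax-invariant)
    row_max = np.where(all_mask > 0, logits.data, -np.inf).max(axis=1, keepdims=True)
    ex = (logits - row_max).exp()
    denom = (ex * all_mask).sum(axis=1, keepdims=True)
    if per_positive:
        k = batch.k_pos
        per_anchor = None
        for col in range(k):
            idx = np.array([p[col] for p in batch.positives])
            p_ex = gather_rows(ex.reshape(-1, 1), np.arange(b) * n_opp + idx)
            term = -(p_ex / denom).log()
            per_anchor = term if per_anchor is None else per_anchor + term
        return (per_anchor / float(k)).mean()
    numer = (ex * pos_mask).sum(axis=1, keepdims=True)
    return -((numer / denom).log()).mean()


def _mine_batches(q_anchor: np.ndarray, q_opposite: np.ndarray, cfg: ContrastiveConfig,
                  rng: np.random.Generator) -> list[ContrastiveBatch]:
    """Score every anchor via the similarity view and sample S+/S− per minibatch."""
    n = q_anchor.shape[0]
    order = rng.permutation(n)
    batches = []
    for start in range(0, n, cfg.batch_size):
        ids = order[start:start + cfg.batch_size]
        pos_sets, neg_sets = [], []
        for a in ids:
            score = cross_view_scores(q_anchor[a], q_opposite)
            pos = sample_positives(score, cfg.k_pos)
            neg = sample_hard_negatives(score, pos, cfg.k_neg,
                                        cfg.hard_pool_fraction, rng)
            pos_sets.append(pos)
            neg_sets.append(neg)
        batches.append(ContrastiveBatch(ids, pos_sets, neg_sets, cfg.k_pos, cfg.k_neg))
    return batches


def co_contrastive_loss(outputs: EncoderOutputs, cfg: ContrastiveConfig,
                        rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    """Drug-anchored and disease-anchored NT-Xent losses (L_r, L_d).

    Pseudo-labels come from the similarity-view embeddings q (no gradient);
    the losses act on the DDA-view embeddings h. Each loss is the mean over
    that type's minibatches of the per-batch anchor-mean NT-Xent.
    """
    losses = []
    for q_a, q_o, h_a, h_o in (
        (outputs.q_drug, outputs.q_disease, outputs.h_drug, outputs.h_disease),
        (outputs.q_disease, outputs.q_drug, outputs.h_disease, outputs.h_drug),
    ):
        batches = _mine_batches(q_a.data, q_o.data, cfg, rng)
        total = None
        n_anchors = 0
        for batch in batches:
            term = ntxent_loss(h_a, h_o, batch, cfg.temperature, cfg.per_positive)
            weighted = term * float(len(batch.anchor_ids))
            total = weighted if total is None else total + weighted
            n_anchors += len(batch.anchor_ids)
        losses.append(total / float(n_anchors))
    return losses[0], losses[1]
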