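"""Decoder, prediction loss, total objective, and the training loop.

The full model: RWR features on each similarity view → per-type projection
perceptrons → bipartite GA/BA encoder (h) and per-type attention encoders on
the kNN views (q) → an MLP decoder scoring every drug-disease pair from
[e_r⊙e_d ‖ h_r ‖ h_d]. Training minimizes weighted binary cross-entropy over
all pairs plus λ times the two NT-Xent co-contrastive losses, with Adam,
per-epoch edge dropout on the message-passing graph, and feature dropout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, concat, gather_rows, xavier_uniform
from .contrastive import ContrastiveConfig, co_contrastive_loss
from .data_io import AssociationMatrix, DatasetBundle
from .encoders import (
    AttentionEncoderParams,
    DdaEncoderParams,
    EncoderOutputs,
    attention_coefficients,
    dda_encode,
    global_scores,
    pair_scores,
    similarity_encode,
)
from .features import FeatureProjector, column_normalize, rwr
from .views import BipartiteView, KnnGraph, build_knn_graph, extended_neighborhoods

__all__ = [
    "TrainConfig",
    "PredictionHead",
    "TrainResult",
    "decode",
    "weighted_bce",
    "total_loss",
    "class_balance_eta",
    "sample_training_negatives",
    "edge_dropout",
    "compute_rwr_features",
    "train",
    "predict_matrix",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """All tunable knobs of the model and its optimization."""

    learning_rate: float = 0.001
    batch_size: int = 64
    restart_prob: float = 0.1
    temperature: float = 0.1
    lambda_ssl: float = 0.1
    beta: float = 0.6
    epochs: int = 100
    patience: int = 30
    edge_dropout_prob: float = 0.1
    layer_dropout_prob: float = 0.1
    embed_dim: int = 64
    knn_k: int = 15
    contrast_k: int = 5
    seed: int = 0
    negative_mode: str = "all"  # "sampled" = equal negatives, unweighted BCE
    rwr_input: str = "knn"      # "similarity" runs RWR on the raw similarity weights

    def __post_init__(self) -> None:
        for name in ("edge_dropout_prob", "layer_dropout_prob"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.restart_prob <= 1:
            raise ValueError("restart_prob must be in (0, 1]")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if self.lambda_ssl < 0:
            raise ValueError("lambda_ssl must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.negative_mode not in ("all", "sampled"):
            raise ValueError("negative_mode must be 'all' or 'sampled'")
        for name in ("batch_size", "epochs", "embed_dim", "knn_k", "contrast_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def contrastive(self) -> ContrastiveConfig:
        return ContrastiveConfig(
            temperature=self.temperature,
            k_pos=self.contrast_k,
            k_neg=self.contrast_k,
            batch_size=self.batch_size,
        )


class PredictionHead:
    """MLP decoder: [e_r⊙e_d ‖ h_r ‖ h_d] (3t) → t ReLU → sigmoid scalar."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.w1 = Tensor(xavier_uniform(rng, 3 * dim, dim), requires_grad=True)
        self.b1 = Tensor(np.zeros(dim), requires_grad=True)
        self.w2 = Tensor(xavier_uniform(rng, dim, 1), requires_grad=True)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3 * self.dim:
            raise ValueError(f"decoder expects width {3 * self.dim}, got {x.shape[1]}")
        hidden = (x @ self.w1 + self.b1).relu()
        return (hidden @ self.w2 + self.b2).sigmoid()


def decode(e_r: Tensor, e_d: Tensor, h_r: Tensor, h_d: Tensor,
           head: PredictionHead) -> Tensor:
    """Score rows of aligned (e_r, e_d, h_r, h_d) batches; returns (n, 1) in (0,1)."""
    return head(concat([e_r * e_d, h_r, h_d], axis=1))


def weighted_bce(predictions: Tensor, labels: np.ndarray, eta: float,
                 literal_negative_term: bool = False) -> Tensor:
    """Class-weighted binary cross-entropy over every scored pair.

        L = −(1/P)[ η Σ_{y=1} log ŷ + Σ_{y=0} log(1−ŷ) ],  P = number of pairs,

    with η the negative:positive ratio of the training fold. The
    ``literal_negative_term`` debug flag replaces log(1−ŷ) with (1−log ŷ);
    that form is unbounded below and is not a supported objective.
    """
    labels = np.asarray(labels, dtype=np.float64).reshape(-1, 1)
    if labels.sum() == 0:
        raise ValueError("training fold contains no positive associations")
    y = predictions.reshape(-1, 1).clip(1e-7, 1.0 - 1e-7)
    pos_term = (y.log() * labels).sum() * eta
    if literal_negative_term:
        neg_term = ((1.0 - y.log()) * (1.0 - labels)).sum()
        return -(pos_term + neg_term) / float(labels.size)
    neg_term = ((1.0 - y).log() * (1.0 - labels)).sum()
    return -(pos_term + neg_term) / float(labels.size)


def total_loss(l_bce: Tensor, l_r: Tensor, l_d: Tensor, lambda_ssl: float) -> Tensor:
    """L = L_bce + λ (L_r + L_d)."""
    if lambda_ssl < 0:
        raise ValueError("lambda_ssl must be non-negative")
    if lambda_ssl == 0:
        return l_bce
    return l_bce + (l_r + l_d) * lambda_ssl


def class_balance_eta(assoc: AssociationMatrix) -> float:
    """η = |S−|/|S+|: the negative:positive ratio of a training matrix."""
    ones = assoc.n_associations
    if ones == 0:
        raise ValueError("training fold contains no positive associations")
    return (assoc.n_drugs * assoc.n_diseases - ones) / ones


def sample_training_negatives(negative_flat_idx: np.ndarray, n_positives: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Uniform draw (no replacement) of |S+| unknown pairs for the sampled-
    negatives training variant."""
    return rng.choice(negative_flat_idx, size=n_positives, replace=False)


def edge_dropout(assoc: AssociationMatrix, prob: float,
                 rng: np.random.Generator) -> BipartiteView:
    """Drop each known association independently with probability ``prob``.

    Affects this epoch's message passing only — the loss labels always come
    from the undropped matrix.
    """
    if not 0 <= prob < 1:
        raise ValueError("dropout probability must be in [0, 1)")
    values = assoc.values
    if prob > 0:
        keep = rng.random(values.shape) >= prob
        values = values * keep
    masked = AssociationMatrix(assoc.drug_ids, assoc.disease_ids, values)
    return extended_neighborhoods(masked)


def _dropout(x: Tensor, prob: float, rng: np.random.Generator) -> Tensor:
    if prob <= 0:
        return x
    mask = (rng.random(x.shape) >= prob) / (1.0 - prob)
    return x * Tensor(mask)


@dataclass
class _Inputs:
    """Fold-independent precomputation: kNN views and RWR feature tables."""

    knn_drug: KnnGraph
    knn_disease: KnnGraph
    x_drug: np.ndarray    # N x N, row i = RWR profile seeded at drug i
    x_disease: np.ndarray


def compute_rwr_features(bundle: DatasetBundle, config: TrainConfig) -> _Inputs:
    """Build the kNN views and run RWR once per node type.

    RWR runs by default on the binary kNN adjacency; ``rwr_input="similarity"``
    uses the raw similarity weights instead.
    """
    knn_r = build_knn_graph(bundle.drug_similarity, config.knn_k)
    knn_d = build_knn_graph(bundle.disease_similarity, config.knn_k)
    if config.rwr_input == "knn":
        src_r, src_d = knn_r.adjacency, knn_d.adjacency
    elif config.rwr_input == "similarity":
        src_r = bundle.drug_similarity.values
        src_d = bundle.disease_similarity.values
    else:
        raise ValueError("rwr_input must be 'knn' or 'similarity'")
    prof_r = rwr(column_normalize(src_r), config.restart_prob).profiles
    prof_d = rwr(column_normalize(src_d), config.restart_prob).profiles
    # column i of the profile matrix is node i's feature vector; profiles are
    # probability vectors (mean entry 1/n), so rescale by n to give the
    # projection perceptron O(1) inputs — a fixed linear conditioning step
    n, m = prof_r.shape[0], prof_d.shape[0]
    return _Inputs(knn_r, knn_d, n * prof_r.T, m * prof_d.T)


class CoContrastiveModel:
    """Parameter bundle plus the forward pass shared by train and predict."""

    def __init__(self, n_drugs: int, n_diseases: int, config: TrainConfig,
                 rng: np.random.Generator):
        t = config.embed_dim
        self.config = config
        self.n_drugs = n_drugs
        self.n_diseases = n_diseases
        self.proj_drug = FeatureProjector(n_drugs, t, rng)
        self.proj_disease = FeatureProjector(n_diseases, t, rng)
        self.dda = DdaEncoderParams.init(t, config.beta, rng)
        self.att_drug = AttentionEncoderParams.init(t, rng)
        self.att_disease = AttentionEncoderParams.init(t, rng)
        self.head = PredictionHead(t, rng)

    @property
    def params(self) -> list[Tensor]:
        return (
            self.proj_drug.params + self.proj_disease.params + self.dda.params
            + self.att_drug.params + self.att_disease.params + self.head.params
        )

    def param_dict(self) -> dict[str, np.ndarray]:
        groups = {
            "proj_drug": self.proj_drug.params,
            "proj_disease": self.proj_disease.params,
            "dda": self.dda.params,
            "att_drug": self.att_drug.params,
            "att_disease": self.att_disease.params,
            "head": self.head.params,
        }
        return {f"{g}.{i}": p.data for g, ps in groups.items() for i, p in enumerate(ps)}

    def load_param_dict(self, arrays: dict[str, np.ndarray]) -> None:
        for key, value in self.param_dict().items():
            value[...] = arrays[key]

    def forward(self, inputs: _Inputs, view: BipartiteView,
                dropout_rng: np.random.Generator | None = None) -> EncoderOutputs:
        cfg = self.config
        training = dropout_rng is not None
        e_r = self.proj_drug(inputs.x_drug)
        e_d = self.proj_disease(inputs.x_disease)
        if training and cfg.layer_dropout_prob > 0:
            e_r = _dropout(e_r, cfg.layer_dropout_prob, dropout_rng)
            e_d = _dropout(e_d, cfg.layer_dropout_prob, dropout_rng)
        e_all = concat([e_r, e_d], axis=0)
        h_all = dda_encode(e_all, view, self.dda)
        if training and cfg.layer_dropout_prob > 0:
            h_all = _dropout(h_all, cfg.layer_dropout_prob, dropout_rng)
        h_r = gather_rows(h_all, np.arange(self.n_drugs))
        h_d = gather_rows(h_all, self.n_drugs + np.arange(self.n_diseases))
        q_r = self._similarity_branch(e_r, h_r, inputs.knn_drug, self.att_drug)
        q_d = self._similarity_branch(e_d, h_d, inputs.knn_disease, self.att_disease)
        return EncoderOutputs(h_drug=h_r, h_disease=h_d, q_drug=q_r, q_disease=q_d,
                              e_drug=e_r, e_disease=e_d)

    @staticmethod
    def _similarity_branch(e: Tensor, h: Tensor, knn: KnnGraph,
                           params: AttentionEncoderParams) -> Tensor:
        eps = global_scores(e, params)
        zeta = pair_scores(e, knn, params)
        delta = attention_coefficients(eps, zeta, knn)
        return similarity_encode(h, delta, knn, params)

    def score_pairs(self, out: EncoderOutputs, drug_idx: np.ndarray,
                    disease_idx: np.ndarray) -> Tensor:
        """Decoder scores for the given (drug, disease) index pairs."""
        return decode(
            gather_rows(out.e_drug, drug_idx),
            gather_rows(out.e_disease, disease_idx),
            gather_rows(out.h_drug, drug_idx),
            gather_rows(out.h_disease, disease_idx),
            self.head,
        )


@dataclass
class TrainResult:
    model: CoContrastiveModel
    loss_trace: list[dict[str, float]] = field(repr=False)
    config: TrainConfig = None
    n_epochs_run: int = 0


def train(bundle: DatasetBundle, config: TrainConfig,
          inputs: _Inputs | None = None) -> TrainResult:
    """Fit the model on all known associations of ``bundle``.

    Per epoch: drop edges from the message-passing view, run both encoders,
    score pairs ("all" mode: every pair with η-weighted BCE; "sampled" mode:
    the positives plus an equal-size uniform draw of unknown pairs,
    unweighted), mine contrastive batches, and take one Adam step on the
    total objective. Early-stops when the loss has not improved for
    ``config.patience`` epochs. Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if inputs is None:
        inputs = compute_rwr_features(bundle, config)
    assoc = bundle.associations
    n, m = assoc.n_drugs, assoc.n_diseases
    model = CoContrastiveModel(n, m, config, rng)
    optimizer = Adam(model.params, lr=config.learning_rate)
    ccfg = config.contrastive()

    labels_flat = assoc.values.astype(np.float64).ravel()
    pos_flat = np.flatnonzero(labels_flat == 1)
    neg_flat = np.flatnonzero(labels_flat == 0)
    eta = class_balance_eta(assoc)
    all_drug_idx = np.repeat(np.arange(n), m)
    all_dis_idx = np.tile(np.arange(m), n)

    trace: list[dict[str, float]] = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        view = edge_dropout(assoc, config.edge_dropout_prob, rng)
        out = model.forward(inputs, view, dropout_rng=rng)

        if config.negative_mode == "all":
            preds = model.score_pairs(out, all_drug_idx, all_dis_idx)
            l_bce = weighted_bce(preds, labels_flat, eta)
        else:  # sampled-negatives variant: |S+| uniform negatives, unweighted BCE
            sampled_neg = sample_training_negatives(neg_flat, pos_flat.size, rng)
            sel = np.concatenate([pos_flat, sampled_neg])
            preds = model.score_pairs(out, sel // m, sel % m)
            l_bce = weighted_bce(preds, labels_flat[sel], 1.0)

        if config.lambda_ssl > 0:
            l_r, l_d = co_contrastive_loss(out, ccfg, rng)
            loss = total_loss(l_bce, l_r, l_d, config.lambda_ssl)
            extras = {"l_r": float(l_r.data), "l_d": float(l_d.data)}
        else:
            loss = l_bce
            extras = {"l_r": 0.0, "l_d": 0.0}

        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: bce={float(l_bce.data)}, "
                f"contrastive={extras}"
            )
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        trace.append({"epoch": epoch, "total": float(loss.data),
                      "bce": float(l_bce.data), **extras})

        if loss.data < best - 1e-5:
            best = float(loss.data)
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    return TrainResult(model=model, loss_trace=trace, config=config,
                       n_epochs_run=len(trace))


def predict_matrix(result: TrainResult, bundle: DatasetBundle,
                   inputs: _Inputs | None = None) -> np.ndarray:
    """Deterministic N x M score matrix (no dropout at inference)."""
    config = result.config
    if inputs is None:
        inputs = compute_rwr_features(bundle, config)
    assoc = bundle.associations
    model = result.model
    view = extended_neighborhoods(assoc)
    out = model.forward(inputs, view, dropout_rng=None)
    n, m = assoc.n_drugs, assoc.n_diseases
    preds = model.score_pairs(out, np.repeat(np.arange(n), m), np.tile(np.arange(m), n))
    return preds.data.reshape(n, m)


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Single .npz archive of parameter arrays plus the JSON-encoded config."""
    arrays = result.model.param_dict()
    meta = {
        "config": asdict(result.config),
        "n_drugs": result.model.n_drugs,
        "n_diseases": result.model.n_diseases,
        "n_epochs_run": result.n_epochs_run,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> TrainResult:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = TrainConfig(**meta["config"])
        rng = np.random.default_rng(config.seed)
        model = CoContrastiveModel(meta["n_drugs"], meta["n_diseases"], config, rng)
        model.load_param_dict({k: data[k] for k in data.files if k != "__meta__"})
    return TrainResult(model=model, loss_trace=[], config=config,
                       n_epochs_run=meta["n_epochs_run"])
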