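"""10-fold cross-validation under the all-negatives protocol, with AUROC,
AUPR, recall@k and a paired t-test.

The protocol follows the benchmark convention for sparse association
matrices: known associations are split into folds; every fold's model trains
on the remaining positives with ALL unknown pairs as negatives, and is
evaluated on its held-out positives against those same unknown pairs. The
negatives are therefore shared between train and test — a documented
property of the protocol, warned about once per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import AssociationMatrix, DatasetBundle
from .model import TrainConfig, compute_rwr_features, predict_matrix, train

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "make_folds",
    "auroc",
    "aupr",
    "recall_at_k",
    "cross_validate",
    "paired_t_test",
]


@dataclass
class FoldSplit:
    """One CV fold over positive pairs; negatives are all original zeros."""

    fold_id: int
    train_positive_pairs: np.ndarray  # (k, 2) [drug, disease] indices
    test_positive_pairs: np.ndarray
    negative_pairs: np.ndarray

    def training_matrix(self, assoc: AssociationMatrix) -> AssociationMatrix:
        """Copy of the association matrix with this fold's test positives masked to 0."""
        values = assoc.values.copy()
        values[self.test_positive_pairs[:, 0], self.test_positive_pairs[:, 1]] = 0
        return AssociationMatrix(assoc.drug_ids, assoc.disease_ids, values)


@dataclass
class MetricsReport:
    per_fold: list[dict[str, float]] = field(default_factory=list)
    per_repetition: list[dict[str, float]] = field(default_factory=list)
    summary: dict[str, float] = field(default_factory=dict)


def make_folds(assoc: AssociationMatrix, n_folds: int,
               rng: np.random.Generator) -> list[FoldSplit]:
    """Shuffle the positive pairs and partition them into near-equal folds."""
    positives = np.argwhere(assoc.values == 1)
    negatives = np.argwhere(assoc.values == 0)
    if n_folds > len(positives):
        raise ValueError(
            f"cannot make {n_folds} folds from {len(positives)} positive pairs"
        )
    perm = rng.permutation(len(positives))
    chunks = np.array_split(perm, n_folds)
    folds = []
    for fold_id, test_idx in enumerate(chunks):
        test_mask = np.zeros(len(positives), dtype=bool)
        test_mask[test_idx] = True
        folds.append(FoldSplit(
            fold_id=fold_id,
            train_positive_pairs=positives[~test_mask],
            test_positive_pairs=positives[test_mask],
            negative_pairs=negatives,
        ))
    return folds


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (equals the Mann-Whitney pair statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision; no trapezoids)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(labels, scores))


def recall_at_k(scores: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Fraction of positives captured in the top-k scored pairs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    top = np.argsort(-scores, kind="stable")[:k]
    return float(labels[top].sum() / labels.sum())


def paired_t_test(metric_a: np.ndarray, metric_b: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t-test over per-repetition metric values."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t statistic undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def evaluate_fold(score_matrix: np.ndarray, fold: FoldSplit,
                  recall_k: int = 100) -> dict[str, float]:
    """Metrics on the fold's held-out positives vs all unknown pairs."""
    test_pos = fold.test_positive_pairs
    neg = fold.negative_pairs
    scores = np.concatenate([
        score_matrix[test_pos[:, 0], test_pos[:, 1]],
        score_matrix[neg[:, 0], neg[:, 1]],
    ])
    labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(neg))])
    return {
        "auroc": auroc(scores, labels),
        "aupr": aupr(scores, labels),
        f"recall@{recall_k}": recall_at_k(scores, labels, recall_k),
    }


def cross_validate(bundle: DatasetBundle, config: TrainConfig, n_repeats: int = 10,
                   n_folds: int = 10, recall_k: int = 100) -> MetricsReport:
    """Repeated n-fold CV; reports per-fold, per-repetition and grand means.

    RWR features depend only on the similarity views, so they are computed
    once and shared across folds. Each repetition reshuffles the fold
    assignment and re-seeds training deterministically from ``config.seed``.
    """
    warnings.warn(
        "all-negatives protocol: every unknown pair serves as a negative in "
        "both training and evaluation",
        stacklevel=2,
    )
    inputs = compute_rwr_features(bundle, config)
    report = MetricsReport()
    metric_keys = ["auroc", "aupr", f"recall@{recall_k}"]
    for rep in range(n_repeats):
        fold_rng = np.random.default_rng((config.seed, rep))
        folds = make_folds(bundle.associations, n_folds, fold_rng)
        rep_metrics = []
        for fold in folds:
            train_assoc = fold.training_matrix(bundle.associations)
            train_bundle = DatasetBundle(train_assoc, bundle.drug_similarity,
                                         bundle.disease_similarity)
            fold_config = TrainConfig(**{
                **config.__dict__,
                "seed": int(np.random.default_rng((config.seed, rep, fold.fold_id))
                            .integers(2 ** 31)),
            })
            result = train(train_bundle, fold_config, inputs=inputs)
            scores = predict_matrix(result, train_bundle, inputs=inputs)
            metrics = evaluate_fold(scores, fold, recall_k)
            report.per_fold.append(
                {"repetition": rep, "fold": fold.fold_id, **metrics}
            )
            rep_metrics.append(metrics)
        report.per_repetition.append(
            {"repetition": rep,
             **{k: float(np.mean([m[k] for m in rep_metrics])) for k in metric_keys}}
        )
    for key in metric_keys:
        values = [r[key] for r in report.per_repetition]
        report.summary[f"{key}_mean"] = float(np.mean(values))
        report.summary[f"{key}_std"] = float(np.std(values))
    return report
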