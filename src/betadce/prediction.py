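"""Classify held-out samples on a selected subset and score with ROC AUC.

A test sample is scored by the beta-posterior mean of P(class A) given
the class counts among its K_used nearest *training* samples; the
predicted class is the one with the larger expectation (ties go to A).
K_used defaults to the rounded median of the training samples' own
optimized neighbor counts — a robust summary of their typically skewed
distribution — and can be fixed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .core import evaluate_subset
from .errors import UndefinedAUCError, ValidationError
from .matrix import CLASS_A, CLASS_B, FeatureMatrix


@dataclass(frozen=True)
class PredictionScore:
    """Score and decision for one test sample."""

    sample_id: str
    score: float  # E[P_A]
    predicted: str  # "A" iff score >= 0.5
    K_used: int


def median_training_k(
    train: FeatureMatrix, subset: Sequence[str], k_max: int | None = None
) -> int:
    """Rounded median of the per-training-sample optimized neighbor counts."""
    evaluation = evaluate_subset(train, subset, k_max=k_max)
    return max(1, int(round(float(np.median(evaluation.sample_K)))))


def score_samples(
    train: FeatureMatrix,
    test_values: np.ndarray,
    subset: Sequence[str],
    test_ids: Sequence[str] | None = None,
    k: int | None = None,
    k_max: int | None = None,
) -> list[PredictionScore]:
    """Score test samples against the training set on a feature subset.

    Parameters
    ----------
    train
        Training matrix; its feature scaling must already have been
        applied to ``test_values`` (standardize the test data with the
        training means/SDs, never its own).
    test_values
        Array of shape (n_test, len(subset)) with columns in the order
        of ``subset``.
    subset
        Selected feature ids, present in ``train``.
    k
        Fixed neighbor count; defaults to the rounded median of the
        training samples' optimized K.
    k_max
        Cap used when deriving the default k from training.
    """
    subset = tuple(subset)
    train_values = train.subset_values(subset)
    test_values = np.atleast_2d(np.asarray(test_values, dtype=np.float64))
    if test_values.shape[1] != len(subset):
        raise ValidationError(
            f"test data has {test_values.shape[1]} columns, subset has {len(subset)}"
        )
    k_used = median_training_k(train, subset, k_max) if k is None else int(k)
    if not 1 <= k_used <= train.n_samples:
        raise ValidationError(f"k must be in 1..{train.n_samples}, got {k_used}")
    ids = (
        tuple(str(s) for s in test_ids)
        if test_ids is not None
        else tuple(f"t{i}" for i in range(test_values.shape[0]))
    )
    d2 = cdist(test_values, train_values, metric="sqeuclidean")
    order = np.argsort(d2, axis=1, kind="stable")[:, :k_used]  # ties: lower index
    is_a = train.is_class_a
    scores = []
    for row, sample_id in zip(order, ids):
        k_a = int(np.sum(is_a[row]))
        e_a = (k_a + 1) / (k_used + 2)
        scores.append(
            PredictionScore(
                sample_id=sample_id,
                score=float(e_a),
                predicted=CLASS_A if e_a >= 0.5 else CLASS_B,
                K_used=k_used,
            )
        )
    return scores


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """AUC as P(random class-A score > random class-B score), ties count 1/2.

    Computed by the rank (Mann-Whitney) formulation; class A is the
    positive class, so scores should be E[P_A]-like.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype="U1")
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_a = int(np.sum(labels == CLASS_A))
    n_b = int(np.sum(labels == CLASS_B))
    if n_a == 0 or n_b == 0:
        raise UndefinedAUCError("AUC needs both classes present")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    rank_sum_a = float(np.sum(ranks[labels == CLASS_A]))
    return (rank_sum_a - n_a * (n_a + 1) / 2) / (n_a * n_b)
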