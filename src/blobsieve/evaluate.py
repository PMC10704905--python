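"""Separation and feature-space diagnostics.

Ground-truth scoring (F1 with blob as the positive class, confusion matrix,
adjusted Rand index, V-measure), internal cluster quality (mean silhouette
coefficient in the standardized feature space that was clustered), and
feature-space structure (Pearson correlation matrix of the five
descriptors, top-2 PCA eigenvectors with explained-variance ratios).

The standard metrics are delegated to scikit-learn; the test suite checks
them against independent brute-force pair-counting / entropy oracles on
small instances.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn import metrics as _skm

from .cluster import ClusterResult, FeatureMatrix
from .geometry import FEATURE_NAMES

__all__ = [
    "EvaluationReport",
    "f1_score",
    "silhouette",
    "adjusted_rand",
    "v_measure",
    "confusion",
    "pcc_matrix",
    "pca_2d",
    "evaluate_separation",
]

LABELS = ("blob", "free")  # row/column order of the confusion matrix


def _check_labels(truth: Sequence[str], predicted: Sequence[str]) -> None:
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if not set(truth) <= set(LABELS) or not set(predicted) <= set(LABELS):
        raise ValueError(f"labels must be in {LABELS}")


def f1_score(truth: Sequence[str], predicted: Sequence[str],
             positive: str = "blob") -> float:
    """Harmonic mean of precision and recall, ``2 TP / (2 TP + FP + FN)``."""
    _check_labels(truth, predicted)
    t = np.asarray(truth) == positive
    p = np.asarray(predicted) == positive
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    if tp + fp + fn == 0:
        raise ValueError("F1 undefined: no positive class present anywhere")
    return 2.0 * tp / (2.0 * tp + fp + fn)


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> np.ndarray:
    """2x2 confusion matrix, rows = truth (blob, free), cols = prediction."""
    _check_labels(truth, predicted)
    return _skm.confusion_matrix(truth, predicted, labels=list(LABELS))


def silhouette(features: FeatureMatrix, assignments: Sequence[int]) -> float:
    """Mean per-sample silhouette coefficient, Euclidean metric.

    Computed in the (standardized) feature space that was clustered: for a
    sample, a = mean intra-cluster distance excluding itself, b = mean
    distance to the nearest other cluster, s = (b - a) / max(a, b).
    """
    labels = np.asarray(assignments)
    if len(labels) != features.n_tracks:
        raise ValueError("one assignment per track required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or np.any(counts == 0):
        raise ValueError("silhouette needs >= 2 non-empty clusters")
    if features.n_tracks < 3:
        raise ValueError("silhouette needs >= 3 samples")
    return float(_skm.silhouette_score(features.values, labels,
                                       metric="euclidean"))


def adjusted_rand(truth: Sequence, predicted: Sequence) -> float:
    """Pair-counting Rand index adjusted for chance (permutation model)."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if len(truth) < 2:
        raise ValueError("ARI needs at least 2 samples")
    return float(_skm.adjusted_rand_score(truth, predicted))


def v_measure(truth: Sequence, predicted: Sequence, beta: float = 1.0) -> float:
    """Harmonic mean of entropy-based homogeneity and completeness."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    return float(_skm.v_measure_score(truth, predicted, beta=beta))


def pcc_matrix(features: FeatureMatrix) -> np.ndarray:
    """Pearson correlation matrix of the five feature axes (5x5)."""
    vals = features.values
    if len(vals) < 2:
        raise ValueError("need at least 2 rows for correlations")
    stds = vals.std(axis=0)
    zero = np.flatnonzero(stds == 0.0)
    if zero.size:
        names = ", ".join(FEATURE_NAMES[i] for i in zero)
        raise ValueError(f"zero-variance feature column(s): {names}")
    pcc = np.corrcoef(vals, rowvar=False)
    np.fill_diagonal(pcc, 1.0)
    return pcc


def pca_2d(features: FeatureMatrix
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-2 principal components of the standardized feature space.

    Returns ``(eigenvectors, evr, projections)``: the two leading
    eigenvectors of the feature covariance (rows, shape 2x5), their
    explained-variance ratios, and the per-track 2D projections.  Each
    eigenvector's sign is fixed so its largest-magnitude entry is positive.
    """
    if not features.standardized:
        raise ValueError("pca_2d expects a standardized FeatureMatrix")
    X = features.values
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 rows")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    if np.count_nonzero(var > var[0] * 1e-12) < 2:
        raise ValueError("feature matrix has rank < 2")
    evr = var / var.sum()
    vecs = vt[:2].copy()
    for row in vecs:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return vecs, evr[:2], Xc @ vecs.T


@dataclass
class EvaluationReport:
    """Everything measured about one pipeline run against ground truth."""

    confusion: np.ndarray
    f1: float
    silhouette: float
    ari: float
    v_measure: float
    b_score_ratio: Optional[float]
    pca_eigenvectors: np.ndarray
    pca_evr: np.ndarray
    pcc: np.ndarray
    n_tracks: int
    n_correct: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "confusion_labels": list(LABELS),
            "f1": self.f1,
            "silhouette": self.silhouette,
            "adjusted_rand_index": self.ari,
            "v_measure": self.v_measure,
            "b_score_ratio": self.b_score_ratio,
            "pca_eigenvectors": self.pca_eigenvectors.tolist(),
            "pca_explained_variance_ratio": self.pca_evr.tolist(),
            "pcc_matrix": self.pcc.tolist(),
            "feature_names": list(FEATURE_NAMES),
            "n_tracks": self.n_tracks,
            "n_correct": self.n_correct,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate_separation(features: FeatureMatrix, result: ClusterResult,
                        truth: dict) -> EvaluationReport:
    """Score an annotated clustering against ground-truth labels.

    ``features`` must be the standardized matrix that was clustered;
    ``truth`` maps track_id to ``"blob"``/``"free"``.
    """
    ids = features.track_ids
    truth_labels = [truth[tid] for tid in ids]
    pred_labels = [result.annotation(tid) for tid in ids]
    assign = [result.assignments[tid] for tid in ids]
    n_correct = int(sum(t == p for t, p in zip(truth_labels, pred_labels)))
    vecs, evr, _ = pca_2d(features)
    return EvaluationReport(
        confusion=confusion(truth_labels, pred_labels),
        f1=f1_score(truth_labels, pred_labels),
        silhouette=silhouette(features, assign),
        ari=adjusted_rand(truth_labels, assign),
        v_measure=v_measure(truth_labels, assign),
        b_score_ratio=result.b_score_ratio,
        pca_eigenvectors=vecs,
        pca_evr=evr,
        pcc=pcc_matrix(features),
        n_tracks=len(ids),
        n_correct=n_correct,
    )
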