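"""Feature-space standardization, single-shot k-means++ and B-score annotation.

The five geometric descriptors live on wildly different scales (nm, nm^2,
dimensionless ratios, nm^-2), so each feature axis is z-scored on the
dataset at hand to zero mean and unit variance before clustering.  A single
greedy-k-means++ initialization followed by Lloyd iterations to convergence
("single-shot": one init, no restarts, no training data) splits the
standardized cloud into k=2 candidate populations.

Which cluster holds the artifacts is decided by the Blob score

    B_cluster = mean over member tracks of (sphericality / d_max)

computed on the *raw* (unstandardized) features: immobile-emitter blobs
combine high sphericality with a small diameter, so the blob cluster has
the larger B by a wide margin, and the ratio max(B)/min(B) measures how
unambiguous the annotation is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .geometry import FEATURE_NAMES, FeatureVector

__all__ = [
    "FeatureMatrix",
    "ClusterResult",
    "standardize",
    "kmeans_separate",
    "blob_score",
    "annotate",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42


@dataclass
class FeatureMatrix:
    """Stacked per-track descriptors, optionally z-scored.

    ``values`` is the working ``(n, 5)`` matrix (raw or standardized);
    ``raw_values`` always keeps the unstandardized descriptors because the
    Blob score is defined on them.  Column order follows
    :data:`~blobsieve.geometry.FEATURE_NAMES`.
    """

    track_ids: list
    values: np.ndarray
    standardized: bool = False
    raw_values: Optional[np.ndarray] = None
    axis_means: Optional[np.ndarray] = None
    axis_stds: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"values must be (n, {len(FEATURE_NAMES)}), got {self.values.shape}"
            )
        if len(self.track_ids) != len(self.values):
            raise ValueError("one track_id per row required")
        if len(set(self.track_ids)) != len(self.track_ids):
            raise ValueError("track_ids must be unique")
        if self.raw_values is None:
            self.raw_values = self.values.copy()

    @classmethod
    def from_features(cls, items: Sequence[tuple[object, FeatureVector]]
                      ) -> "FeatureMatrix":
        ids = [tid for tid, _ in items]
        vals = np.array([fv.as_array() for _, fv in items])
        return cls(track_ids=ids, values=vals)

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(FEATURE_NAMES),
                            index=pd.Index(self.track_ids, name="track_id"))


@dataclass
class ClusterResult:
    """Two-way k-means split with optional blob/free annotation.

    ``assignments`` maps track_id to cluster index; ``centers`` are in the
    standardized feature space.  After :func:`annotate`, ``blob_cluster``
    names the cluster with the larger Blob score and ``b_score_ratio`` is
    ``max(B)/min(B) >= 1``.
    """

    assignments: dict
    centers: np.ndarray
    seed: int
    blob_scores: Optional[np.ndarray] = None
    blob_cluster: Optional[int] = None
    b_score_ratio: Optional[float] = None

    @property
    def labels(self) -> np.ndarray:
        return np.array(list(self.assignments.values()))

    def annotation(self, track_id) -> str:
        """Return ``"blob"`` or ``"free"`` for one track (requires annotate)."""
        if self.blob_cluster is None:
            raise ValueError("result not annotated yet; call annotate()")
        return "blob" if self.assignments[track_id] == self.blob_cluster else "free"

    def to_label_frame(self) -> pd.DataFrame:
        rows = [
            {
                "track_id": tid,
                "cluster": c,
                "annotation": (
                    "" if self.blob_cluster is None
                    else ("blob" if c == self.blob_cluster else "free")
                ),
            }
            for tid, c in self.assignments.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "centers": self.centers.tolist(),
                "blob_scores": None if self.blob_scores is None
                else self.blob_scores.tolist(),
                "blob_cluster": self.blob_cluster,
                "b_score_ratio": self.b_score_ratio,
                "seed": self.seed,
            },
            indent=2,
        )


def standardize(features: FeatureMatrix) -> FeatureMatrix:
    """Z-score every feature axis independently (population 1/N variance).

    The statistics are computed on this dataset alone, and the (means, stds)
    pair used is retained so the transform is invertible.  A zero-variance
    column cannot be standardized and raises, naming the feature.
    """
    if features.n_tracks < 2:
        raise ValueError("need at least 2 rows to standardize")
    vals = features.values
    means = vals.mean(axis=0)
    stds = vals.std(axis=0)  # population (ddof=0) convention
    zero = np.flatnonzero(stds == 0.0)
    if zero.size:
        names = ", ".join(FEATURE_NAMES[i] for i in zero)
        raise ValueError(f"zero-variance feature column(s): {names}")
    return FeatureMatrix(
        track_ids=list(features.track_ids),
        values=(vals - means) / stds,
        standardized=True,
        raw_values=features.raw_values.copy(),
        axis_means=means,
        axis_stds=stds,
    )


def kmeans_separate(features: FeatureMatrix, k: int = 2,
                    seed: int = DEFAULT_SEED) -> ClusterResult:
    """Single-shot greedy k-means++ split of the standardized feature space.

    Exactly one greedy k-means++ initialization (``n_init=1``) is followed
    by Lloyd iterations to convergence; the result is deterministic for a
    fixed seed.  Centers are reported in the standardized space.
    """
    if not features.standardized:
        raise ValueError("kmeans_separate expects a standardized FeatureMatrix")
    if features.n_tracks < k:
        raise ValueError(f"need at least k={k} rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    labels = km.fit_predict(features.values)
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        raise RuntimeError(
            f"empty cluster after convergence (sizes {sizes.tolist()}); "
            "try a different seed"
        )
    logger.info("k-means split: sizes=%s, seed=%d", sizes.tolist(), seed)
    return ClusterResult(
        assignments=dict(zip(features.track_ids, (int(c) for c in labels))),
        centers=km.cluster_centers_.copy(),
        seed=seed,
    )


def blob_score(raw_features: np.ndarray) -> float:
    """Blob score of one cluster: mean of sphericality / d_max over members.

    ``raw_features`` is the ``(m, 5)`` block of *unstandardized* descriptors
    of the cluster's member tracks.
    """
    raw_features = np.asarray(raw_features, dtype=float)
    if raw_features.ndim != 2 or len(raw_features) == 0:
        raise ValueError("blob_score needs a non-empty (m, 5) feature block")
    i_sphe = FEATURE_NAMES.index("sphericality")
    i_dmax = FEATURE_NAMES.index("d_max")
    return float((raw_features[:, i_sphe] / raw_features[:, i_dmax]).mean())


def annotate(result: ClusterResult, features: FeatureMatrix,
             tie_tol: float = 1e-12) -> ClusterResult:
    """Mark the cluster with the larger Blob score as the blob cluster.

    Only meaningful for k=2.  The annotation is invariant under relabeling
    of the internal cluster indices; a B-score tie (within ``tie_tol``)
    is ambiguous and raises.
    """
    labels = np.array([result.assignments[tid] for tid in features.track_ids])
    k = result.centers.shape[0]
    if k != 2:
        raise ValueError("B-score annotation applies to k=2 only")
    scores = np.empty(k)
    for c in range(k):
        members = features.raw_values[labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        scores[c] = blob_score(members)
    if abs(scores[0] - scores[1]) <= tie_tol:
        raise ValueError(
            f"ambiguous annotation: B-scores tied at {scores[0]:.3e}"
        )
    result.blob_scores = scores
    result.blob_cluster = int(np.argmax(scores))
    result.b_score_ratio = float(scores.max() / scores.min())
    logger.info("B-scores %s -> blob cluster %d (ratio %.1f)",
                scores.tolist(), result.blob_cluster, result.b_score_ratio)
    return result
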