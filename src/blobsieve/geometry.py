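"""Per-trajectory geometric descriptors.

A single-particle trajectory is treated as an unordered point cloud
``P = {x_1, ..., x_N}`` in 2D or 3D.  Five scalar descriptors summarise its
shape:

``d_max``
    Maximum Euclidean distance between any two localizations (the diameter
    of the cloud).
``hull_measure``
    Area (2D) or volume (3D) of the convex hull of ``P``, computed with
    Qhull via :class:`scipy.spatial.ConvexHull`.
``ellipticity``
    Ratio of the hull measure to the measure of an ellipse (2D,
    ``pi * d_max * d_mean``) or ellipsoid (3D, ``4*pi/3 * d_max * d_mean**2``)
    built from the diameter and the mean distance ``d_mean`` of the points to
    their center of mass.
``sphericality``
    Ratio of the hull measure to that of the circle (``pi * d_mean**2``) or
    sphere (``4*pi/3 * d_mean**3``) of radius ``d_mean``.
``density``
    Number of localizations per unit hull measure, ``N / hull_measure``.

Immobilized emitters produce tight, isotropic clouds (small ``d_max``, high
``sphericality`` and ``density``); free diffusion produces elongated,
irregular hulls.  All five descriptors are invariant under rigid motions and
permutation of the points; ``ellipticity`` and ``sphericality`` are
additionally invariant under uniform rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "TrackPointCloud",
    "FeatureVector",
    "DegenerateTrackError",
    "max_distance",
    "center_stats",
    "convex_hull_measure",
    "ellipticity",
    "center_sphericality",
    "convex_density",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("d_max", "hull_measure", "ellipticity", "sphericality", "density")


class DegenerateTrackError(ValueError):
    """Raised when a point cloud cannot support the geometric descriptors.

    Covers too few points (``N < dim + 1``), zero-measure convex hulls
    (collinear in 2D, coplanar in 3D) and clouds collapsed onto a single
    point (``d_mean == 0``).  Carries the offending ``track_id`` when known.
    """

    def __init__(self, message: str, track_id=None):
        self.track_id = track_id
        if track_id is not None:
            message = f"track {track_id!r}: {message}"
        super().__init__(message)


@dataclass
class TrackPointCloud:
    """One trajectory: ordered localizations with optional times and label.

    Parameters
    ----------
    track_id
        Opaque identifier, unique within a dataset.
    points
        ``(N, dim)`` array of coordinates, in the input's native length
        unit (nm by convention).
    times
        Optional ``(N,)`` array of non-decreasing timestamps in seconds.
    label
        Optional ground-truth tag, one of ``"blob"``, ``"free"``,
        ``"unknown"``.
    """

    track_id: object
    points: np.ndarray
    times: Optional[np.ndarray] = None
    label: str = "unknown"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2D array of shape (N, dim)")
        if self.points.shape[1] not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.points.shape[1]}")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (len(self.points),):
                raise ValueError("times must have one entry per point")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("timestamps must be non-decreasing")
        if self.label not in ("blob", "free", "unknown"):
            raise ValueError(f"label must be blob/free/unknown, got {self.label!r}")

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FeatureVector:
    """The five geometric descriptors of one track."""

    d_max: float
    hull_measure: float
    ellipticity: float
    sphericality: float
    density: float
    dim: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.d_max, self.hull_measure, self.ellipticity,
             self.sphericality, self.density]
        )


def _diameter(pts: np.ndarray) -> float:
    # explicit coordinate differences (no expanded dot products), so the
    # result agrees bitwise with a naive per-pair sqrt-of-squares scan
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def max_distance(track: TrackPointCloud) -> float:
    """Maximum Euclidean distance between any two localizations.

    The diameter of a point set is attained at a pair of convex-hull
    vertices, so for large clouds the pairwise scan is restricted to hull
    vertices; small or hull-degenerate clouds fall back to the full
    O(N^2) scan.
    """
    pts = track.points
    if len(pts) < 2:
        raise DegenerateTrackError("need at least 2 points for d_max",
                                   track.track_id)
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate hull: diameter still well defined, scan all
    return _diameter(pts)


def center_stats(track: TrackPointCloud) -> tuple[np.ndarray, float]:
    """Center of mass and mean distance of the points to it.

    Returns ``(mu, d_mean)`` where ``mu`` is the arithmetic mean of the
    coordinates and ``d_mean = mean_i ||x_i - mu||``.
    """
    pts = track.points
    if len(pts) == 0:
        raise DegenerateTrackError("empty track", track.track_id)
    mu = pts.mean(axis=0)
    d_mean = float(np.linalg.norm(pts - mu, axis=1).mean())
    return mu, d_mean


def convex_hull_measure(track: TrackPointCloud) -> float:
    """Convex hull area (2D) or volume (3D) via Qhull."""
    pts = track.points
    if len(pts) < track.dim + 1:
        raise DegenerateTrackError(
            f"need at least dim+1={track.dim + 1} points for a convex hull",
            track.track_id,
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateTrackError(
            f"degenerate (zero-measure) convex hull: {exc}", track.track_id
        ) from exc
    # ConvexHull.volume is the area in 2D and the volume in 3D
    measure = float(hull.volume)
    if measure <= 0.0:
        raise DegenerateTrackError("zero-measure convex hull", track.track_id)
    return measure


def _elli(measure: float, d_max: float, d_mean: float, dim: int) -> float:
    if d_max <= 0 or d_mean <= 0:
        raise DegenerateTrackError("zero d_max or d_mean in ellipticity")
    if dim == 2:
        return measure / (math.pi * d_max * d_mean)
    return measure / (4.0 * math.pi / 3.0 * d_max * d_mean ** 2)


def _sphe(measure: float, d_mean: float, dim: int) -> float:
    if d_mean <= 0:
        raise DegenerateTrackError("zero d_mean in sphericality")
    if dim == 2:
        return measure / (math.pi * d_mean ** 2)
    return measure / (4.0 * math.pi / 3.0 * d_mean ** 3)


def ellipticity(track: TrackPointCloud) -> float:
    """Hull measure relative to the ellipse/ellipsoid spanned by d_max, d_mean."""
    _, d_mean = center_stats(track)
    try:
        return _elli(convex_hull_measure(track), max_distance(track), d_mean,
                     track.dim)
    except DegenerateTrackError as exc:
        raise DegenerateTrackError(str(exc), track.track_id) from exc


def center_sphericality(track: TrackPointCloud) -> float:
    """Hull measure relative to the circle/sphere of radius d_mean."""
    _, d_mean = center_stats(track)
    try:
        return _sphe(convex_hull_measure(track), d_mean, track.dim)
    except DegenerateTrackError as exc:
        raise DegenerateTrackError(str(exc), track.track_id) from exc


def convex_density(track: TrackPointCloud) -> float:
    """Localizations per unit hull measure, ``N / hull_measure``."""
    return track.n_points / convex_hull_measure(track)


def extract_features(track: TrackPointCloud) -> FeatureVector:
    """Compute all five descriptors from one hull/center computation."""
    pts = track.points
    dim = track.dim
    if len(pts) < dim + 1:
        raise DegenerateTrackError(
            f"need at least dim+1={dim + 1} points", track.track_id
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateTrackError(
            f"degenerate (zero-measure) convex hull: {exc}", track.track_id
        ) from exc
    measure = float(hull.volume)
    if measure <= 0.0:
        raise DegenerateTrackError("zero-measure convex hull", track.track_id)
    d_max = _diameter(pts[hull.vertices])
    mu = pts.mean(axis=0)
    d_mean = float(np.linalg.norm(pts - mu, axis=1).mean())
    if d_max <= 0 or d_mean <= 0:
        raise DegenerateTrackError("point cloud collapsed to a single point",
                                   track.track_id)
    return FeatureVector(
        d_max=d_max,
        hull_measure=measure,
        ellipticity=_elli(measure, d_max, d_mean, dim),
        sphericality=_sphe(measure, d_mean, dim),
        density=len(pts) / measure,
        dim=dim,
    )
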