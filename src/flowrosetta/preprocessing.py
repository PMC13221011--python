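"""Cluster discovery and per-cluster standardization.

Before any model fitting, the pipeline (i) finds the optimal clustering by
silhouette-scored k-means (or accepts caller-provided labels), (ii) rotates
each cluster so its principal axis lies on a coordinate axis, recording the
exact transform so synthetic replicates can later be placed back into the
original sample geometry, and (iii) permanently removes per-dimension z-score
outliers, recording the truncation window so downstream fitting can account
for it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .generator import LabeledEvents

__all__ = [
    "RosettaConfig",
    "ClusterTransform",
    "DirectionUndefinedError",
    "find_optimal_clusters",
    "principal_angle",
    "axis_to_rotation",
    "rotate_to_axis",
    "remove_outliers",
    "outlier_window",
    "apply_inverse",
    "SILHOUETTE_WARN_LEVEL",
    "SILHOUETTE_EXACT_MAX_N",
]

logger = logging.getLogger(__name__)

#: Below this silhouette the clustering is flagged as possibly suboptimal.
SILHOUETTE_WARN_LEVEL = 0.25
#: Above this many events, silhouette is evaluated on a seeded subsample
#: (exact silhouette is O(N^2)).
SILHOUETTE_EXACT_MAX_N = 20_000


class DirectionUndefinedError(ValueError):
    """Raised when a cluster is too isotropic for a principal direction."""


@dataclass(frozen=True)
class RosettaConfig:
    """Run options controlling clustering, fitting, rotation and trimming.

    Component ranges are per-dimension (x, y) pairs.  ``tolerance`` is the
    EM convergence threshold on the largest scaled parameter change per
    iteration; ``mean_step_limit`` caps each component-mean update to that
    fraction of the component's current scale (the documented stabilizer of
    the fitting stage; set to ``None`` to disable).  Outlier thresholds are
    per-dimension z-score cutoffs in SD units.
    """

    min_clusters: int = 2
    max_clusters: int = 5
    min_components_per_cluster: tuple[int, int] = (1, 1)
    max_components_per_cluster: tuple[int, int] = (2, 2)
    use_cluster_id: bool = False
    max_iterations: int = 100
    tolerance: float = 1e-3
    angle_method: str = "vertical"
    outer_percent: float = 2.0
    threshold_x: float = 3.5
    threshold_y: float = 3.5
    mean_step_limit: float | None = 0.05

    def __post_init__(self) -> None:
        if self.min_clusters > self.max_clusters:
            raise ValueError("min_clusters must be <= max_clusters")
        if not self.use_cluster_id and self.min_clusters < 2:
            raise ValueError("silhouette selection needs min_clusters >= 2")
        for lo, hi in zip(self.min_components_per_cluster, self.max_components_per_cluster):
            if lo < 1 or lo > hi:
                raise ValueError("component ranges must satisfy 1 <= min <= max")
        if self.angle_method not in ("vertical", "horizontal"):
            raise ValueError("angle_method must be 'vertical' or 'horizontal'")
        if not (0.0 <= self.outer_percent < 100.0):
            raise ValueError("outer_percent must be in [0, 100)")
        if self.threshold_x <= 0 or self.threshold_y <= 0:
            raise ValueError("outlier thresholds must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class ClusterTransform:
    """Centroid shift and rotation taking a cluster to analysis orientation.

    Alignment subtracts ``centroid`` then rotates counter-clockwise by
    ``rotation_deg`` (the principal-axis angle, clockwise from vertical, in
    [0, 180)); for horizontal alignment an extra 90 degrees is folded in.
    ``apply_inverse`` undoes both exactly.
    """

    centroid: tuple[float, float]
    rotation_deg: float

    def matrix(self) -> NDArray[np.float64]:
        """Rotation matrix applied to (already centered) row vectors."""
        th = math.radians(self.rotation_deg)
        # counter-clockwise by rotation_deg, acting on column (x, y)
        return np.array([[math.cos(th), -math.sin(th)],
                         [math.sin(th), math.cos(th)]])


def silhouette_coefficient(values: NDArray[np.float64], labels: NDArray[np.int64]) -> float:
    """Exact mean silhouette coefficient (Euclidean), computed in row chunks.

    Memory stays at chunk x N rather than N x N; singleton clusters score 0
    by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = values.shape[0]
    counts = np.bincount(inv, minlength=k).astype(float)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    s_sum = 0.0
    chunk = max(1, int(2**22 // max(n, 1)))
    for start in range(0, n, chunk):
        rows = slice(start, min(start + chunk, n))
        d = cdist(values[rows], values)           # (m, N)
        sums = d @ onehot                          # (m, k): total distance per cluster
        own = inv[rows]
        m = sums.shape[0]
        a_den = counts[own] - 1.0
        a = np.where(a_den > 0, sums[np.arange(m), own] / np.maximum(a_den, 1.0), np.nan)
        means = sums / counts
        means[np.arange(m), own] = np.inf
        b = means.min(axis=1)
        s = np.where(np.isnan(a), 0.0, (b - a) / np.maximum(a, b))
        s_sum += float(s.sum())
    return s_sum / n


def _silhouette(values: NDArray[np.float64], labels: NDArray[np.int64],
                rng: np.random.Generator) -> float:
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if values.shape[0] > SILHOUETTE_EXACT_MAX_N:
        idx = rng.choice(values.shape[0], SILHOUETTE_EXACT_MAX_N, replace=False)
        values, labels = values[idx], labels[idx]
        if len(np.unique(labels)) < 2:  # pathological subsample
            return -1.0
    return silhouette_coefficient(values, labels)


def find_optimal_clusters(
    events: LabeledEvents,
    cfg: RosettaConfig,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[NDArray[np.int64], int, float]:
    """Cluster the events and score the clustering.

    With ``cfg.use_cluster_id`` the input labels pass through unchanged and
    only the silhouette is computed.  Otherwise k-means (k-means++, 10
    restarts, seeded) is run for each k in [min_clusters, max_clusters] and
    the k with the highest silhouette wins; silhouette ties break toward
    smaller k.
    """
    rng = np.random.default_rng(seed)
    values = events.values
    if cfg.use_cluster_id:
        labels = events.labels.copy()
        uniq = np.unique(labels[labels >= 0])
        if uniq.size < 1:
            raise ValueError("use_cluster_id requires labelled events")
        if uniq.size == 1:
            sil = math.nan  # single cluster: silhouette undefined
        else:
            sil = _silhouette(values, labels, rng)
        k = int(uniq.size)
    else:
        if len(events) < 2 * cfg.min_clusters:
            raise ValueError("not enough events for the requested cluster range")
        best: tuple[float, int, NDArray[np.int64]] | None = None
        km_seed = int(rng.integers(2**31 - 1))
        for k_try in range(cfg.min_clusters, cfg.max_clusters + 1):
            km = KMeans(n_clusters=k_try, n_init=10, random_state=km_seed)
            lab = km.fit_predict(values)
            s = _silhouette(values, lab.astype(np.int64), rng)
            if best is None or s > best[0] + 1e-12:
                best = (s, k_try, lab.astype(np.int64))
        assert best is not None
        sil, k, labels = best
    if not math.isnan(sil) and sil < SILHOUETTE_WARN_LEVEL:
        logger.warning(
            "silhouette %.3f < %.2f: clustering results may be suboptimal",
            sil, SILHOUETTE_WARN_LEVEL)
    return labels, k, float(sil)


def principal_angle(points: NDArray[np.float64], outer_percent: float = 2.0) -> float:
    """Principal-axis angle, clockwise from vertical, in [0, 180).

    The ``outer_percent`` of points farthest (Euclidean) from the centroid
    are excluded from the covariance *for this computation only*, shielding
    the direction estimate from stray outliers.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be N x 2")
    centered = pts - pts.mean(axis=0)
    if outer_percent > 0:
        r = np.hypot(centered[:, 0], centered[:, 1])
        cut = np.percentile(r, 100.0 - outer_percent)
        centered = centered[r <= cut]
    if centered.shape[0] < 3:
        raise ValueError("need at least 3 points after trimming")
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] / max(evals[0], 1e-300) < 1.01:
        raise DirectionUndefinedError(
            f"near-isotropic cluster (eigenvalue ratio {evals[1] / evals[0]:.4f} < 1.01): "
            "principal direction undefined")
    major = evecs[:, 1]  # eigh sorts ascending
    # angle of the axis clockwise from vertical (+Y); axis defined mod 180
    return float(np.degrees(np.arctan2(major[0], major[1])) % 180.0)


def axis_to_rotation(angle_deg: float) -> float:
    """Report an axis angle as a direction in [0, 360).

    The principal axis is defined mod 180; for reporting, the representative
    whose direction vector points into the upper half-plane (positive
    vertical component) is used, giving values in [270, 360) or [0, 90].
    """
    a = float(angle_deg) % 180.0
    return a if a <= 90.0 else a + 180.0


def rotate_to_axis(
    points: NDArray[np.float64],
    angle_method: str = "vertical",
    outer_percent: float = 2.0,
) -> tuple[NDArray[np.float64], ClusterTransform]:
    """Center a cluster and rotate its principal axis onto a coordinate axis.

    ``vertical`` puts the maximum-variance axis on +Y, ``horizontal`` on +X.
    Returns the rotated points and the exact transform applied.
    """
    if angle_method not in ("vertical", "horizontal"):
        raise ValueError("angle_method must be 'vertical' or 'horizontal'")
    pts = np.asarray(points, dtype=float)
    angle = principal_angle(pts, outer_percent)
    if angle_method == "horizontal":
        angle = angle - 90.0  # counter-clockwise by theta-90 puts the axis on +X
    centroid = pts.mean(axis=0)
    tr = ClusterTransform(centroid=(float(centroid[0]), float(centroid[1])),
                          rotation_deg=float(angle))
    rotated = (pts - centroid) @ tr.matrix().T
    return rotated, tr


def remove_outliers(
    points: NDArray[np.float64],
    threshold_x: float,
    threshold_y: float,
) -> NDArray[np.float64]:
    """Drop points with |z-score| beyond the per-dimension thresholds.

    Z-scores are computed from the mean and SD of the *input* points; removal
    is permanent for downstream fitting.
    """
    keep = _outlier_mask(points, threshold_x, threshold_y)
    if not keep.any():
        raise ValueError("outlier thresholds removed every point")
    return np.asarray(points, dtype=float)[keep]


def outlier_window(
    points: NDArray[np.float64],
    threshold_x: float,
    threshold_y: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """The ((x_lo, x_hi), (y_lo, y_hi)) window kept by ``remove_outliers``."""
    if threshold_x <= 0 or threshold_y <= 0:
        raise ValueError("thresholds must be > 0")
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0)
    return ((float(mean[0] - threshold_x * sd[0]), float(mean[0] + threshold_x * sd[0])),
            (float(mean[1] - threshold_y * sd[1]), float(mean[1] + threshold_y * sd[1])))


def _outlier_mask(points, threshold_x, threshold_y):
    (xlo, xhi), (ylo, yhi) = outlier_window(points, threshold_x, threshold_y)
    pts = np.asarray(points, dtype=float)
    return ((pts[:, 0] >= xlo) & (pts[:, 0] <= xhi)
            & (pts[:, 1] >= ylo) & (pts[:, 1] <= yhi))


def apply_inverse(points: NDArray[np.float64], transform: ClusterTransform) -> NDArray[np.float64]:
    """Undo ``rotate_to_axis``: rotate back and restore the centroid."""
    pts = np.asarray(points, dtype=float)
    return pts @ transform.matrix() + np.asarray(transform.centroid)
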