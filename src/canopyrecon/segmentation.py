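"""Ground leveling, plant/soil colour split, and per-plant clustering.

The cleaned row cloud is leveled so the soil plane (found by RANSAC)
becomes z = 0, split into vegetation and soil by the excess-green index
2G - B - R thresholded with Otsu's method, clustered into individual
plants by density clustering (DBSCAN, 40 points within 0.04 m), and
over-segmented clusters are merged by the row-axis interval containment
rule before cropping each plant out of the full-resolution cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .cloud import ColoredPointCloud
from .geometry import RigidTransform, rotation_aligning
from .preprocessing import voxel_downsample

__all__ = [
    "PlaneModel",
    "ClusterBounds",
    "SegmentationParams",
    "fit_ground_plane",
    "level_cloud",
    "exg_index",
    "otsu_threshold",
    "color_segment",
    "density_cluster",
    "merge_clusters",
    "extract_plants",
    "segment_plants",
]


@dataclass(frozen=True)
class PlaneModel:
    """Plane n . p + d = 0 with |n| = 1."""

    n: np.ndarray
    d: float
    inlier_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self):
        n = np.asarray(self.n, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "n", n / norm)
        object.__setattr__(self, "d", float(self.d) / norm)
        object.__setattr__(
            self, "inlier_indices", np.asarray(self.inlier_indices, dtype=int)
        )

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.n + self.d

    def flipped(self) -> "PlaneModel":
        return PlaneModel(-self.n, -self.d, self.inlier_indices)


@dataclass
class ClusterBounds:
    """Axis-aligned bounds of one cluster plus its member point indices."""

    mins: np.ndarray
    maxs: np.ndarray
    member_indices: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float).reshape(3)
        self.maxs = np.asarray(self.maxs, dtype=float).reshape(3)
        if np.any(self.mins > self.maxs):
            raise ValueError("bounds must satisfy min <= max per axis")
        self.member_indices = np.asarray(self.member_indices, dtype=int)

    def center(self, axis: int = 1) -> float:
        """Midpoint of the cluster's interval along ``axis``."""
        return float((self.mins[axis] + self.maxs[axis]) / 2.0)

    def extent(self, axis: int = 1) -> float:
        return float(self.maxs[axis] - self.mins[axis])

    @classmethod
    def from_points(cls, points: np.ndarray, member_indices) -> "ClusterBounds":
        pts = np.atleast_2d(points)
        return cls(pts.min(axis=0), pts.max(axis=0), member_indices)


@dataclass(frozen=True)
class SegmentationParams:
    eps: float = 0.04
    min_points: int = 40
    margin: float = 0.002
    ransac_dist: float = 0.005
    ransac_iters: int = 1000
    cluster_voxel: float = 0.005  # downsample before clustering, for speed
    row_axis: int = 1

    def __post_init__(self):
        if min(self.eps, self.margin, self.ransac_dist, self.cluster_voxel) <= 0:
            raise ValueError("scales must be positive")
        if self.min_points < 1 or self.ransac_iters < 1:
            raise ValueError("counts must be >= 1")


# ---------------------------------------------------------------------------
# ground plane


def fit_ground_plane(
    cloud: ColoredPointCloud,
    dist_thresh: float = 0.005,
    iters: int = 1000,
    seed: int = 0,
) -> PlaneModel:
    """RANSAC plane fit, refined by least squares on the inlier set.

    Random 3-point samples propose planes; the plane with the most points
    within ``dist_thresh`` wins and is refit by PCA over its inliers.  The
    normal is oriented so that n_z >= 0.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points")
    rng = np.random.default_rng(seed)
    best_count = -1
    best_normal, best_d = None, None
    n_pts = len(pts)
    for _ in range(iters):
        i, j, k = rng.choice(n_pts, size=3, replace=False)
        v1, v2 = pts[j] - pts[i], pts[k] - pts[i]
        n = np.cross(v1, v2)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue  # collinear sample
        n = n / norm
        d = -float(n @ pts[i])
        count = int(np.sum(np.abs(pts @ n + d) <= dist_thresh))
        if count > best_count:
            best_count, best_normal, best_d = count, n, d
        if n_pts == 3:
            break
    if best_normal is None:
        raise ValueError("degenerate cloud: all RANSAC samples collinear")

    inliers = np.nonzero(np.abs(pts @ best_normal + best_d) <= dist_thresh)[0]
    if len(inliers) >= 3:
        sub = pts[inliers]
        centroid = sub.mean(axis=0)
        _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
        n = vt[-1]
        if np.linalg.norm(n) > 1e-12:
            best_normal = n
            best_d = -float(n @ centroid)
    if best_normal[2] < 0:
        best_normal, best_d = -best_normal, -best_d
    return PlaneModel(best_normal, best_d, inliers)


def level_cloud(
    cloud: ColoredPointCloud, plane: PlaneModel
) -> tuple[ColoredPointCloud, RigidTransform]:
    """Rotate the plane normal onto +z and shift the plane to z = 0."""
    R = rotation_aligning(plane.n, [0.0, 0.0, 1.0])
    # after rotation the plane is z + d = 0; translate by +d along z
    T = RigidTransform.from_translation([0, 0, plane.d]) @ (
        RigidTransform.from_rotation_translation(R, [0, 0, 0])
    )
    return cloud.transformed(T), T


# ---------------------------------------------------------------------------
# colour split


def exg_index(colors: np.ndarray) -> np.ndarray:
    """Excess-green index 2G - B - R on a 0-255 colour scale."""
    c = np.atleast_2d(np.asarray(colors, dtype=float))
    if np.any(c < 0) or np.any(c > 255):
        raise ValueError("colours must lie in [0, 255]")
    return 2.0 * c[:, 1] - c[:, 2] - c[:, 0]


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Histogram threshold maximising between-class variance.

    Values are histogrammed into ``bins`` equal cells over [min, max]; the
    returned threshold is the interior bin edge with the largest
    between-class variance, ties broken toward the lower edge.  Classes
    are (value <= threshold) vs (value > threshold).
    """
    v = np.asarray(values, dtype=float).ravel()
    if len(v) < 2:
        raise ValueError("need at least two values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("cannot threshold constant values")
    hist, edges = np.histogram(v, bins=bins, range=(lo, hi))
    hist = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    mass = np.cumsum(hist * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mass / w0
        mu1 = (mass[-1] - mass) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-1.0)
    k = int(np.argmax(var_between))  # argmax takes the first (lowest) on ties
    return float(edges[k + 1])


def color_segment(
    cloud: ColoredPointCloud,
) -> tuple[ColoredPointCloud, ColoredPointCloud]:
    """Split the cloud into (plant, soil) by excess green + Otsu.

    Vegetation scores high on 2G - B - R; the Otsu threshold separates the
    green foreground from the soil background.  A constant-colour cloud
    yields an empty plant partition with a warning.
    """
    if len(cloud) == 0:
        raise ValueError("cannot colour-segment an empty cloud")
    idx = exg_index(cloud.colors * 255.0)
    if idx.max() == idx.min():
        warnings.warn("constant-colour cloud: no vegetation found, all soil")
        return cloud.select(np.zeros(len(cloud), bool)), cloud.select(slice(None))
    t = otsu_threshold(idx)
    plant_mask = idx > t
    return cloud.select(plant_mask), cloud.select(~plant_mask)


# ---------------------------------------------------------------------------
# clustering


def density_cluster(
    cloud: ColoredPointCloud, eps: float = 0.04, min_points: int = 40
) -> list[ClusterBounds]:
    """Density clustering with DBSCAN semantics.

    A core point has at least ``min_points`` points (itself included)
    within ``eps``; clusters are the density-connected components, noise
    points belong to no cluster.  Returns per-cluster axis-aligned bounds.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if len(cloud) == 0:
        return []
    labels = DBSCAN(eps=eps, min_samples=min_points).fit(cloud.points).labels_
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        members = np.nonzero(labels == lab)[0]
        clusters.append(ClusterBounds.from_points(cloud.points[members], members))
    return clusters


def merge_clusters(
    clusters: list[ClusterBounds], axis: int = 1
) -> list[ClusterBounds]:
    """Merge over-segmented clusters by row-axis interval containment.

    Density clustering splits plants whose parts are farther than eps
    apart (e.g. separate leaves).  Whenever a cluster's row-axis centre
    lies inside another cluster's row-axis interval, the cluster is
    absorbed (bounds and members unioned) into the containing cluster —
    choosing, among multiple candidates, the one with the largest row-axis
    extent.  Repeats until no centre lies inside another's interval.
    Clusters are processed in ascending order of interval minimum, so the
    result is deterministic; each absorption removes one cluster, so the
    fixpoint arrives in at most n - 1 absorptions.
    """
    work = [
        ClusterBounds(c.mins.copy(), c.maxs.copy(), c.member_indices.copy())
        for c in clusters
    ]
    changed = True
    while changed and len(work) > 1:
        changed = False
        work.sort(key=lambda c: c.mins[axis])
        for i, ci in enumerate(work):
            center = ci.center(axis)
            candidates = [
                j
                for j, cj in enumerate(work)
                if j != i and cj.mins[axis] <= center <= cj.maxs[axis]
            ]
            if not candidates:
                continue
            j = max(candidates, key=lambda j: work[j].extent(axis))
            cj = work[j]
            merged = ClusterBounds(
                np.minimum(ci.mins, cj.mins),
                np.maximum(ci.maxs, cj.maxs),
                np.concatenate([cj.member_indices, ci.member_indices]),
            )
            work[j] = merged
            del work[i]
            changed = True
            break
    return work


def extract_plants(
    full_cloud: ColoredPointCloud,
    merged: list[ClusterBounds],
    margin: float = 0.002,
) -> list[ColoredPointCloud]:
    """Crop one plant candidate per merged cluster from the full cloud.

    Bounds are expanded by ``margin`` on all six faces; the crop box is
    closed at the lower bound and open at the upper bound so abutting
    boxes partition space.  Empty crops are dropped with a warning.
    """
    plants = []
    for k, c in enumerate(merged):
        lo = c.mins - margin
        hi = c.maxs + margin
        mask = np.all(
            (full_cloud.points >= lo) & (full_cloud.points < hi), axis=1
        )
        if not mask.any():
            warnings.warn(f"cluster {k}: empty crop, dropped")
            continue
        plants.append(full_cloud.select(mask))
    return plants


def segment_plants(
    plant_cloud: ColoredPointCloud,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[ColoredPointCloud], list[ClusterBounds]]:
    """Cluster the vegetation cloud into individual plants.

    Clustering runs on a voxel-downsampled copy for speed; the crops are
    taken from the full-resolution vegetation cloud.
    """
    coarse = voxel_downsample(plant_cloud, params.cluster_voxel)
    clusters = density_cluster(coarse, params.eps, params.min_points)
    merged = merge_clusters(clusters, axis=params.row_axis)
    plants = extract_plants(plant_cloud, merged, params.margin)
    return plants, merged
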