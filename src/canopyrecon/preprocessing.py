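"""Row-cloud denoising: statistical outlier removal, radius filter, voxel grid.

Sensor noise and registration residue leave stray points around the merged
row cloud.  The cleaning chain runs in a fixed order: statistical outlier
removal (global mean-kNN-distance criterion), radius filter (local support
within 2 mm), then voxel averaging into a 1 mm grid.  The radius/voxel
defaults follow the full-resolution sensor footprint; both are parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud

__all__ = [
    "FilterParams",
    "statistical_outlier_removal",
    "radius_filter",
    "voxel_downsample",
    "clean_cloud",
]


@dataclass(frozen=True)
class FilterParams:
    stat_k: int = 20
    stat_std_ratio: float = 2.0
    radius: float = 0.002
    min_neighbors: int = 12
    voxel: float = 0.001

    def __post_init__(self):
        if min(self.stat_k, self.min_neighbors) < 1:
            raise ValueError("neighbour counts must be >= 1")
        if min(self.stat_std_ratio, self.radius, self.voxel) <= 0:
            raise ValueError("filter scales must be positive")


def statistical_outlier_removal(
    cloud: ColoredPointCloud, k: int = 20, std_ratio: float = 2.0
) -> ColoredPointCloud:
    """Drop points whose mean k-NN distance is anomalously large.

    A point is removed when its mean distance to its k nearest neighbours
    exceeds (global mean + std_ratio * global std) of those means.  Clouds
    with fewer than k+1 points are returned unchanged with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cloud) <= k:
        warnings.warn(
            f"cloud of {len(cloud)} points too small for k={k} statistical "
            "filter; returned unchanged"
        )
        return cloud.select(slice(None))
    tree = cKDTree(cloud.points)
    # k+1 because the nearest neighbour of every point is itself
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + std_ratio * mean_d.std()
    return cloud.select(mean_d <= cutoff)


def radius_filter(
    cloud: ColoredPointCloud, radius: float = 0.002, min_neighbors: int = 12
) -> ColoredPointCloud:
    """Keep points with at least ``min_neighbors`` others within ``radius``.

    The neighbour count excludes the query point itself.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(cloud) <= min_neighbors:
        return cloud.select(np.zeros(len(cloud), dtype=bool))
    tree = cKDTree(cloud.points)
    # equivalent to counting neighbours in the ball, but much cheaper:
    # a point has >= m neighbours within r iff its m-th nearest
    # neighbour (excluding itself) lies within r
    dists, _ = tree.query(
        cloud.points,
        k=min_neighbors + 1,
        distance_upper_bound=np.nextafter(radius, np.inf),  # inclusive ball
    )
    return cloud.select(np.isfinite(dists[:, min_neighbors]))


def voxel_downsample(cloud: ColoredPointCloud, voxel: float = 0.001) -> ColoredPointCloud:
    """Average points (and colours) within each cell of an origin-anchored grid.

    Cells are ``floor(coordinate / voxel)`` per axis — anchored at the
    coordinate origin, so crops of the same cloud bucket identically.
    """
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    if len(cloud) == 0:
        return cloud.select(slice(None))
    idx = np.floor(cloud.points / voxel).astype(np.int64)
    _, inverse, counts = np.unique(
        idx, axis=0, return_inverse=True, return_counts=True
    )
    n_cells = len(counts)
    pts = np.zeros((n_cells, 3))
    cols = np.zeros((n_cells, 3))
    np.add.at(pts, inverse, cloud.points)
    np.add.at(cols, inverse, cloud.colors)
    pts /= counts[:, None]
    cols /= counts[:, None]
    return ColoredPointCloud(pts, cols)


def clean_cloud(cloud: ColoredPointCloud, params: FilterParams = FilterParams()):
    """Full cleaning chain: statistical -> radius -> voxel."""
    out = statistical_outlier_removal(cloud, params.stat_k, params.stat_std_ratio)
    out = radius_filter(out, params.radius, params.min_neighbors)
    return voxel_downsample(out, params.voxel)
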