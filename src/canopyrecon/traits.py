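"""Per-plant canopy traits: height, leaf surface area, projected area.

Height is the maximal signed distance from plant points to the fitted soil
plane.  Leaf area triangulates the (manually clipped or synthetic) leaf
cloud: points are projected onto their PCA best-fit plane, Delaunay
triangulated in 2-D, long sliver triangles pruned, and the 3-D triangle
areas summed — so a curved leaf's area exceeds its ground projection, as
it should.  Projected canopy area discards z and counts occupied cells of
an origin-anchored XY grid (1 mm cells at full sensor resolution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .cloud import ColoredPointCloud
from .segmentation import PlaneModel

__all__ = [
    "GridSpec",
    "PlantRecord",
    "plant_height",
    "leaf_area",
    "projected_area",
    "trait_report",
]


@dataclass(frozen=True)
class GridSpec:
    cell: float = 0.001

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("grid cell must be positive")


@dataclass
class PlantRecord:
    plant_id: int
    cloud: ColoredPointCloud
    height: float = np.nan
    projected_area: float = np.nan
    leaf_areas: list = field(default_factory=list)


def plant_height(plant_cloud: ColoredPointCloud, plane: PlaneModel) -> float:
    """Distance from the highest plant point to the soil plane.

    ``plane`` must be oriented with its normal pointing up (toward the
    canopy); the height is then the maximum signed point-to-plane
    distance.  A non-positive height signals a segmentation failure and
    warns.
    """
    if len(plant_cloud) == 0:
        raise ValueError("empty plant cloud")
    h = float(plane.signed_distance(plant_cloud.points).max())
    if h <= 0:
        warnings.warn(
            "all plant points on or below the soil plane: height <= 0 "
            "(possible segmentation failure)"
        )
    return h


def leaf_area(leaf_cloud: ColoredPointCloud, prune_edge: float = 0.01) -> float:
    """Leaf surface area by faceting the leaf point cloud.

    Points are projected to their PCA best-fit plane, triangulated with a
    2-D Delaunay mesh, triangles whose longest 3-D edge exceeds
    ``prune_edge`` are discarded (they bridge concavities of the leaf
    outline), and the remaining 3-D triangle areas are summed.
    """
    pts = leaf_cloud.points
    if len(pts) < 3:
        raise ValueError("leaf area needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12:
        raise ValueError("collinear leaf points cannot be faceted")
    uv = centered @ vt[:2].T
    try:
        tri = Delaunay(uv)
    except QhullError as exc:
        raise ValueError(f"degenerate leaf cloud: {exc}") from exc
    a = pts[tri.simplices[:, 0]]
    b = pts[tri.simplices[:, 1]]
    c = pts[tri.simplices[:, 2]]
    edges = np.stack(
        [
            np.linalg.norm(b - a, axis=1),
            np.linalg.norm(c - b, axis=1),
            np.linalg.norm(a - c, axis=1),
        ]
    )
    keep = edges.max(axis=0) <= prune_edge
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    return float(areas[keep].sum())


def projected_area(
    plant_cloud: ColoredPointCloud, grid: GridSpec = GridSpec()
) -> float:
    """Canopy area projected onto the XY plane.

    Points are bucketed by floor(coordinate / cell) on x and y (grid
    anchored at the origin); the area is the occupied-cell count times
    cell².
    """
    if len(plant_cloud) == 0:
        raise ValueError("empty plant cloud")
    ij = np.floor(plant_cloud.points[:, :2] / grid.cell).astype(np.int64)
    n_cells = len(np.unique(ij, axis=0))
    return float(n_cells * grid.cell**2)


def trait_report(plants: list[PlantRecord], path) -> pd.DataFrame:
    """Write one CSV row per plant, ordered by plant id."""
    rows = []
    for p in sorted(plants, key=lambda p: p.plant_id):
        rows.append(
            {
                "plant_id": p.plant_id,
                "n_points": len(p.cloud),
                "height_m": round(float(p.height), 6),
                "projected_area_m2": round(float(p.projected_area), 6),
                "leaf_area_total_m2": (
                    round(float(np.sum(p.leaf_areas)), 6) if p.leaf_areas else ""
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "plant_id", "n_points", "height_m",
            "projected_area_m2", "leaf_area_total_m2",
        ],
    )
    df.to_csv(path, index=False)
    return df
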