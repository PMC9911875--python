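"""Pairwise colored ICP and crop-row fusion.

Selected frames are fused into one row cloud in the first frame's camera
coordinates.  Each new frame enters with the coarse pure-translation
matrix S built from its estimated platform displacement — without it, fine
matching on repetitive canopy/soil texture falls into local optima — and
is refined by colored ICP (Park, Zhou & Koltun 2017): a joint objective

    E(T) = (1 - delta) * E_color(T) + delta * E_geometric(T)

where E_geometric is the point-to-plane residual over correspondences
within ``max_corr_dist`` and E_color penalises the difference between a
source point's intensity and the target's locally linearised intensity on
the tangent plane.  The photometric term is what pins down sliding along
the (nearly planar) soil, which pure point-to-plane leaves unconstrained.

The solve is Gauss-Newton on the se(3) increment, run coarse-to-fine over
a voxel pyramid (4x, 2x, 1x, 0.5x ``max_corr_dist``); the finest level
resolves the scene texture that the photometric term localises against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .camera import DEPTH_MAX_DEFAULT, DEPTH_MIN_DEFAULT, frame_to_pointcloud
from .cloud import ColoredPointCloud
from .frame_selection import FrameSelection, build_coarse_transform
from .geometry import RigidTransform, rotation_about_axis
from .preprocessing import voxel_downsample

__all__ = [
    "RegistrationError",
    "RegistrationResult",
    "RegistrationParams",
    "RowReconstruction",
    "apply_transform",
    "estimate_normals",
    "colored_icp",
    "reconstruct_row",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    fitness: float  # fraction of source points with an inlier correspondence
    inlier_rmse: float  # metres

    def __post_init__(self):
        if not 0.0 <= self.fitness <= 1.0 or self.inlier_rmse < 0:
            raise ValueError("invalid fitness / rmse")


@dataclass(frozen=True)
class RegistrationParams:
    max_corr_dist: float = 0.01
    delta: float = 0.968  # geometric weight; photometric weight is 1 - delta
    max_iter: int = 50
    normal_k: int = 30
    pyramid_factors: tuple = (4.0, 2.0, 1.0, 0.5)
    crop_margin: float = 0.05
    depth_min: float = DEPTH_MIN_DEFAULT
    depth_max: float = DEPTH_MAX_DEFAULT

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.max_corr_dist <= 0:
            raise ValueError("max_corr_dist must be positive")


def apply_transform(cloud: ColoredPointCloud, T: RigidTransform) -> ColoredPointCloud:
    """Affine image of the cloud under T; colours unchanged."""
    return cloud.transformed(T)


def estimate_normals(
    points: np.ndarray, k: int = 30, viewpoint=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Per-point unit normals by PCA over k nearest neighbours.

    Normals are oriented toward ``viewpoint`` (the camera origin), so a
    ground plane seen from above points back at the sensor.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    k = min(k, n - 1)
    if k < 2:
        raise ValueError("need at least 3 points for normal estimation")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    nbrs = pts[idx]  # (n, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue direction
    flip = np.einsum("ni,ni->n", normals, np.asarray(viewpoint) - pts) < 0
    normals[flip] *= -1
    return normals


def _intensity(colors: np.ndarray) -> np.ndarray:
    c = np.asarray(colors, dtype=float)
    return 0.299 * c[:, 0] + 0.587 * c[:, 1] + 0.114 * c[:, 2]


def _color_gradients(
    points: np.ndarray, intensity: np.ndarray, normals: np.ndarray, k: int = 15
) -> np.ndarray:
    """Tangent-plane intensity gradient d_p at each target point.

    d_p minimises sum over neighbours q' of
    (C(q) + d_p . (f(q') - q) - C(q'))^2 subject to d_p . n = 0, where f
    projects onto the tangent plane at q.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    k = min(k, n - 1)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    nbr_off = pts[idx[:, 1:]] - pts[:, None, :]  # (n, k, 3)
    # project neighbour offsets onto each tangent plane
    along_n = np.einsum("nkj,nj->nk", nbr_off, normals)
    tang = nbr_off - along_n[..., None] * normals[:, None, :]
    dI = intensity[idx[:, 1:]] - intensity[:, None]
    A = np.einsum("nki,nkj->nij", tang, tang)
    # pin the normal direction so the 3x3 systems stay invertible
    A += normals[:, :, None] * normals[:, None, :]
    A += 1e-12 * np.eye(3)
    b = np.einsum("nki,nk->ni", tang, dI)
    return np.linalg.solve(A, b[..., None])[..., 0]


def _se3_increment(xi: np.ndarray) -> RigidTransform:
    """Small-motion transform from a 6-vector (omega, t)."""
    R = rotation_about_axis(xi[:3], float(np.linalg.norm(xi[:3])))
    return RigidTransform.from_rotation_translation(R, xi[3:])


def _gauss_newton_level(
    src_pts,
    src_int,
    tgt_pts,
    tgt_int,
    tgt_normals,
    tgt_grad,
    init: RigidTransform,
    corr_dist: float,
    delta: float,
    max_iter: int,
    tol: float = 1e-6,
) -> tuple[RigidTransform, bool]:
    T = init
    tree = cKDTree(tgt_pts)
    found_any = False
    for _ in range(max_iter):
        s = T.apply(src_pts)
        dist, j = tree.query(s, distance_upper_bound=corr_dist)
        ok = np.isfinite(dist)
        if ok.sum() < 6:
            break
        found_any = True
        si, ji = s[ok], j[ok]
        q = tgt_pts[ji]
        n = tgt_normals[ji]
        diff = si - q

        r_g = np.einsum("ni,ni->n", diff, n)
        J_g = np.concatenate([np.cross(si, n), n], axis=1)  # (m, 6)

        d = tgt_grad[ji]
        r_c = np.einsum("ni,ni->n", diff, d) + tgt_int[ji] - src_int[ok]
        J_c = np.concatenate([np.cross(si, d), d], axis=1)

        wg, wc = delta, 1.0 - delta
        H = wg * J_g.T @ J_g + wc * J_c.T @ J_c
        g = wg * J_g.T @ r_g + wc * J_c.T @ r_c
        # damped solve: directions the correspondences barely constrain
        # (e.g. in-plane slide under a geometry-only fit of a plane) would
        # otherwise random-walk on residual noise; Tikhonov damping at
        # 1e-4 of the largest eigenvalue pins them near zero while leaving
        # well-constrained directions effectively untouched
        eigval, eigvec = np.linalg.eigh(H)
        if eigval[-1] <= 0:
            break
        lam = 1e-4 * eigval[-1]
        xi = -(eigvec @ ((eigvec.T @ g) / (eigval + lam)))
        # trust region: a step beyond the correspondence radius is
        # extrapolating past its own data support (on near-planar scenes a
        # weakly constrained in-plane direction would otherwise let the
        # estimate jump to an aliased texture period)
        t_norm = np.linalg.norm(xi[3:])
        if t_norm > corr_dist:
            xi = xi * (corr_dist / t_norm)
        T = _se3_increment(xi) @ T
        if np.linalg.norm(xi) < tol:
            break
    return T, found_any


def colored_icp(
    source: ColoredPointCloud,
    target: ColoredPointCloud,
    init: RigidTransform | None = None,
    max_corr_dist: float = 0.01,
    delta: float = 0.968,
    max_iter: int = 50,
    normal_k: int = 30,
    pyramid_factors: tuple = (4.0, 2.0, 1.0, 0.5),
) -> RegistrationResult:
    """Refine the rigid transform taking ``source`` onto ``target``.

    Coarse-to-fine over a voxel pyramid (cells ``pyramid_factors`` times
    ``max_corr_dist``); per level the correspondence radius equals the
    voxel size.  Convergence when the parameter-update norm drops below
    1e-6 or ``max_iter`` iterations are spent.

    Raises :class:`RegistrationError` when no correspondences lie within
    reach at the initial alignment (fitness 0).
    """
    if len(source) == 0 or len(target) == 0:
        raise RegistrationError("cannot register empty clouds")
    T = RigidTransform.identity() if init is None else init
    found_any = False
    iters = [max_iter] + [
        max(max_iter // (k + 2), 5) for k in range(len(pyramid_factors) - 1)
    ]
    for factor, n_it in zip(pyramid_factors, iters):
        voxel = factor * max_corr_dist
        src = voxel_downsample(source, voxel)
        tgt = voxel_downsample(target, voxel)
        if len(tgt) < 4 or len(src) < 4:
            continue
        nk = min(normal_k, len(tgt) - 1)
        normals = estimate_normals(tgt.points, k=nk)
        grads = _color_gradients(
            tgt.points, _intensity(tgt.colors), normals, k=min(15, len(tgt) - 1)
        )
        # photometric residuals are only meaningful where the voxel grid
        # resolves the scene texture; coarser levels run point-to-plane
        # only (their gradients alias and can drag a good initialisation
        # toward a false texture period)
        level_delta = delta if factor <= 1.0 else 1.0
        T, found = _gauss_newton_level(
            src.points,
            _intensity(src.colors),
            tgt.points,
            _intensity(tgt.colors),
            normals,
            grads,
            T,
            corr_dist=voxel,
            delta=level_delta,
            max_iter=n_it,
        )
        found_any = found_any or found

    # fitness / rmse at the requested correspondence distance
    tree = cKDTree(target.points)
    dist, _ = tree.query(T.apply(source.points), distance_upper_bound=max_corr_dist)
    inlier = np.isfinite(dist)
    fitness = float(inlier.mean()) if len(dist) else 0.0
    rmse = float(np.sqrt(np.mean(dist[inlier] ** 2))) if inlier.any() else 0.0
    if not found_any or fitness == 0.0:
        raise RegistrationError(
            "registration failed: no correspondences within "
            f"{max_corr_dist} m of the initial alignment (fitness 0)"
        )
    return RegistrationResult(transform=T, fitness=fitness, inlier_rmse=rmse)


@dataclass
class RowReconstruction:
    cloud: ColoredPointCloud
    poses: list  # RigidTransform per selected frame (frame -> row coords)
    results: list = field(default_factory=list)  # RegistrationResult per pair


def _crop(cloud: ColoredPointCloud, lo, hi) -> ColoredPointCloud:
    m = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    return cloud.select(m)


def reconstruct_row(
    frames,
    selection: FrameSelection,
    params: RegistrationParams = RegistrationParams(),
) -> RowReconstruction:
    """Fuse the selected frames into one row cloud.

    The first selected frame anchors the row coordinate system.  Each
    subsequent frame is initialised with its coarse matrix S composed onto
    the accumulated pose, refined by colored ICP against the accumulated
    cloud (cropped to the incoming frame's neighbourhood for speed), then
    transformed and concatenated.  A failed registration aborts with the
    offending frame index.
    """
    by_index = {f.index: f for f in frames}
    missing = [i for i in selection.selected_indices if i not in by_index]
    if missing:
        raise KeyError(f"selected frame indices missing from stream: {missing}")

    first = by_index[selection.selected_indices[0]]
    accumulated = [
        frame_to_pointcloud(first, params.depth_min, params.depth_max)
    ]
    poses = [RigidTransform.identity()]
    results: list[RegistrationResult] = []
    merged = accumulated[0]

    for idx, (dx, dy) in zip(
        selection.selected_indices[1:], selection.displacements[1:]
    ):
        cloud_i = frame_to_pointcloud(by_index[idx], params.depth_min, params.depth_max)
        S = build_coarse_transform(dx, dy)
        init = poses[-1] @ S
        guess = cloud_i.transformed(init)
        lo, hi = guess.bounds()
        target = _crop(merged, lo - params.crop_margin, hi + params.crop_margin)
        if len(target) == 0:
            raise RegistrationError(
                f"frame {idx}: coarse alignment has no overlap with the row"
            )
        try:
            res = colored_icp(
                cloud_i,
                target,
                init=init,
                max_corr_dist=params.max_corr_dist,
                delta=params.delta,
                max_iter=params.max_iter,
                normal_k=params.normal_k,
                pyramid_factors=params.pyramid_factors,
            )
        except RegistrationError as exc:
            raise RegistrationError(f"frame {idx}: {exc}") from exc
        poses.append(res.transform)
        results.append(res)
        accumulated.append(cloud_i.transformed(res.transform))
        merged = ColoredPointCloud.concatenate(accumulated)

    return RowReconstruction(cloud=merged, poses=poses, results=results)
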