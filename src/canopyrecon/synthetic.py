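"""Ground-truthed synthetic crop rows and RGB-D sweep rendering.

The generator emulates the acquisition geometry of a row-phenotyping
platform: a downward-looking RGB-D camera 1.1 m above the ground, moving
along a row of seedling-sized plants over textured soil at 0.2–0.6 m/s,
recording at 30 Hz.  Scenes are triangle meshes — a speckled soil plane at
z = 0, and per plant a thin vertical stem prism plus parametric curved
leaves whose analytic surface areas are known from fine subdivision — so
every pipeline stage can be tested against construction-time ground truth
without any field data.

World coordinates: x along the row, y across, z up.  The sensor's x axis
points opposite the platform motion and its z axis at the ground, so the
camera-to-world rotation is diag(-1, 1, -1).

Rendering is a deterministic software rasteriser: pinhole projection with
a z-buffer, flat per-face colours (the viewpoint-stable speckle texture
that feature detectors key on), additive Gaussian depth noise, and
per-pixel colour jitter (sensor noise, not viewpoint-stable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .camera import CameraExtrinsics, CameraIntrinsics, RGBDFrame
from .cloud import ColoredPointCloud

__all__ = [
    "SceneSpec",
    "CameraTrack",
    "GroundTruth",
    "TriangleScene",
    "default_intrinsics",
    "generate_scene",
    "render_frame",
    "render_sequence",
    "labeled_row_cloud",
]

#: camera-to-world rotation for the downward-looking sensor
CAM_TO_WORLD = np.diag([-1.0, 1.0, -1.0])

SOIL_LABEL = -1


@dataclass(frozen=True)
class SceneSpec:
    n_plants: int = 5
    plant_spacing: float = 0.18
    stem_height_range: tuple = (0.10, 0.20)
    leaves_per_plant: tuple = (3, 5)
    leaf_size_range: tuple = (0.03, 0.05)  # leaf length in metres
    soil_extent: float = 0.6  # soil margin beyond the row, each side
    soil_half_width: float = 0.45
    soil_cell: float = 0.02  # soil texture face size
    texture_noise: float = 15.0 / 255.0  # per-face speckle std (scene texture)
    pixel_noise: float = 2.0 / 255.0  # per-pixel colour jitter std (sensor)
    depth_noise_sigma: float = 0.001  # metres
    stem_width: float = 0.012
    seed: int = 0

    def __post_init__(self):
        if self.plant_spacing <= 0:
            raise ValueError("plant spacing must be positive")
        for rng_ in (self.stem_height_range, self.leaves_per_plant, self.leaf_size_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range {rng_} must be ordered")


@dataclass(frozen=True)
class CameraTrack:
    speed: float  # m/s along +x (the platform direction)
    track_length: float  # metres
    height_above_ground: float = 1.1
    fps: float = 30.0
    start_x: float = 0.0
    y: float = 0.0

    def __post_init__(self):
        if self.speed <= 0 or self.fps <= 0:
            raise ValueError("speed and fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.track_length / (self.speed / self.fps))) + 1

    def positions(self) -> np.ndarray:
        """(n_frames, 3) world camera centres; spacing exactly speed/fps."""
        k = np.arange(self.n_frames)
        x = self.start_x + k * (self.speed / self.fps)
        return np.column_stack(
            [x, np.full_like(x, self.y), np.full_like(x, self.height_above_ground)]
        )


@dataclass
class TriangleScene:
    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    face_colors: np.ndarray  # (F, 3) in [0, 1]
    face_labels: np.ndarray  # (F,) plant id, SOIL_LABEL for soil

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass
class GroundTruth:
    heights: np.ndarray  # per-plant stem-top height above soil (m)
    leaf_areas: list  # per plant: list of analytic leaf areas (m^2)
    projected_areas: np.ndarray  # per-plant canopy area at projected_cell (m^2)
    projected_cell: float
    plant_centers: np.ndarray  # (n, 2) stem base positions

    def to_dict(self) -> dict:
        return {
            "heights": [float(h) for h in self.heights],
            "leaf_areas": [[float(a) for a in la] for la in self.leaf_areas],
            "projected_areas": [float(a) for a in self.projected_areas],
            "projected_cell": float(self.projected_cell),
            "plant_centers": self.plant_centers.tolist(),
        }


def default_intrinsics(width: int = 424, height: int = 240) -> CameraIntrinsics:
    """Pinhole intrinsics for a native-resolution sensor mode.

    Focal length scales with width so the field of view (~52 deg
    horizontal) is resolution-independent.
    """
    fx = 430.0 * width / 424.0
    return CameraIntrinsics(
        fx=fx, fy=fx, cx=width / 2.0, cy=height / 2.0,
        width=width, height=height, depth_scale=0.001,
    )


# ---------------------------------------------------------------------------
# scene construction


def _leaf_surface(base, azimuth, length, half_width, rise, droop):
    """Parametric leaf: P(s, t) for s in [0,1] (base->tip), t in [-1,1]."""
    u = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    side = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])

    def P(s, t):
        s = np.asarray(s, dtype=float)[..., None]
        t = np.asarray(t, dtype=float)[..., None]
        lift = rise * s - droop * s**2
        w = half_width * np.sin(np.pi * s)
        return base + u * (length * s) + np.array([0.0, 0.0, 1.0]) * lift + side * (w * t)

    return P


def _mesh_patch(P, ns: int, nt: int):
    """Triangulate a parametric patch on an (ns+1) x (nt+1) grid."""
    s = np.linspace(0.0, 1.0, ns + 1)
    t = np.linspace(-1.0, 1.0, nt + 1)
    S, T = np.meshgrid(s, t, indexing="ij")
    verts = P(S.ravel(), T.ravel())
    faces = []
    for i in range(ns):
        for j in range(nt):
            a = i * (nt + 1) + j
            b = a + 1
            c = a + (nt + 1)
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return verts, np.asarray(faces, dtype=int)


def _patch_area(P, ns: int = 240, nt: int = 24) -> float:
    verts, faces = _mesh_patch(P, ns, nt)
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(np.sum(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)))


def _box_prism(cx, cy, half, z0, z1):
    """Vertical square prism (4 sides + top) as vertices/faces."""
    xs = [cx - half, cx + half]
    ys = [cy - half, cy + half]
    v = np.array(
        [[x, y, z] for z in (z0, z1) for y in ys for x in xs], dtype=float
    )
    # bottom ring 0..3 (z0), top ring 4..7 (z1); ring order: (x-,y-),(x+,y-),(x-,y+),(x+,y+)
    quads = [
        (0, 1, 5, 4),  # y- side
        (1, 3, 7, 5),  # x+ side
        (3, 2, 6, 7),  # y+ side
        (2, 0, 4, 6),  # x- side
        (4, 5, 7, 6),  # top
    ]
    faces = []
    for a, b, c, d in quads:
        faces.append([a, b, c])
        faces.append([a, c, d])
    return v, np.asarray(faces, dtype=int)


SOIL_BASE = np.array([0.45, 0.33, 0.25])
STEM_BASE = np.array([0.20, 0.38, 0.15])
LEAF_BASE = np.array([0.15, 0.45, 0.12])


def generate_scene(
    spec: SceneSpec, projected_cell: float = 0.002
) -> tuple[TriangleScene, GroundTruth]:
    """Build a deterministic ground-truthed row scene.

    Plants sit at x = i * spacing, y = 0 (the row runs along x).  Raises
    when plants at the given spacing would overlap laterally.
    """
    rng = np.random.default_rng(spec.seed)
    row_len = (spec.n_plants - 1) * spec.plant_spacing

    all_v: list[np.ndarray] = []
    all_f: list[np.ndarray] = []
    all_c: list[np.ndarray] = []
    all_l: list[np.ndarray] = []
    offset = 0

    def add(verts, faces, base_color, label, jitter_rng):
        nonlocal offset
        all_v.append(verts)
        all_f.append(faces + offset)
        # albedo speckle: brightness-dominant (channel-correlated) with a
        # small chromatic component — real soil/leaf texture varies in
        # luminance far more than in hue, which is what keeps the
        # excess-green index bimodal between soil and vegetation
        lum = jitter_rng.normal(0.0, spec.texture_noise, size=(len(faces), 1))
        chroma = jitter_rng.normal(0.0, spec.texture_noise / 5.0, size=(len(faces), 3))
        all_c.append(np.clip(base_color + lum + chroma, 0.0, 1.0))
        all_l.append(np.full(len(faces), label, dtype=int))
        offset += len(verts)

    # soil plane, one speckled cell at a time
    x_lo, x_hi = -spec.soil_extent, row_len + spec.soil_extent
    y_lo, y_hi = -spec.soil_half_width, spec.soil_half_width
    nx = max(1, int(np.ceil((x_hi - x_lo) / spec.soil_cell)))
    ny = max(1, int(np.ceil((y_hi - y_lo) / spec.soil_cell)))
    gx = np.linspace(x_lo, x_hi, nx + 1)
    gy = np.linspace(y_lo, y_hi, ny + 1)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    soil_v = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    soil_f = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = a + 1
            c = a + (ny + 1)
            d = c + 1
            soil_f.append([a, c, b])
            soil_f.append([b, c, d])
    add(soil_v, np.asarray(soil_f, dtype=int), SOIL_BASE, SOIL_LABEL, rng)

    heights = np.zeros(spec.n_plants)
    leaf_areas: list[list[float]] = []
    centers = np.zeros((spec.n_plants, 2))
    plant_reach = np.zeros(spec.n_plants)
    plant_face_slices: list[slice] = []

    for p in range(spec.n_plants):
        cx = p * spec.plant_spacing
        cy = float(rng.uniform(-0.01, 0.01))
        centers[p] = (cx, cy)
        h = float(rng.uniform(*spec.stem_height_range))
        heights[p] = h
        face_start = sum(len(f) for f in all_f)

        sv, sf = _box_prism(cx, cy, spec.stem_width / 2.0, 0.0, h)
        add(sv, sf, STEM_BASE, p, rng)

        n_leaves = int(rng.integers(spec.leaves_per_plant[0], spec.leaves_per_plant[1] + 1))
        areas = []
        reach = spec.stem_width / 2.0
        for k in range(n_leaves):
            L = float(rng.uniform(*spec.leaf_size_range))
            azim = float(rng.uniform(0, 2 * np.pi))
            attach = float(rng.uniform(0.3, 0.7)) * h
            rise = 0.3 * L
            droop = 1.5 * rise  # tip ends below the attachment point
            half_w = 0.2 * L
            base = np.array([cx, cy, attach])
            P = _leaf_surface(base, azim, L, half_w, rise, droop)
            lv, lf = _mesh_patch(P, ns=12, nt=6)
            add(lv, lf, LEAF_BASE, p, rng)
            areas.append(_patch_area(P))
            reach = max(reach, L + spec.stem_width / 2.0)
        leaf_areas.append(areas)
        plant_reach[p] = reach
        plant_face_slices.append(slice(face_start, sum(len(f) for f in all_f)))

    for p in range(spec.n_plants - 1):
        if plant_reach[p] + plant_reach[p + 1] >= spec.plant_spacing:
            raise ValueError(
                f"plants {p} and {p + 1} overlap at spacing "
                f"{spec.plant_spacing} m: spacing too small"
            )

    scene = TriangleScene(
        vertices=np.vstack(all_v),
        faces=np.vstack(all_f),
        face_colors=np.vstack(all_c),
        face_labels=np.concatenate(all_l),
    )
    projected = np.array(
        [
            _faces_projected_area(scene, plant_face_slices[p], projected_cell)
            for p in range(spec.n_plants)
        ]
    )
    gt = GroundTruth(
        heights=heights,
        leaf_areas=leaf_areas,
        projected_areas=projected,
        projected_cell=projected_cell,
        plant_centers=centers,
    )
    return scene, gt


def _faces_projected_area(scene: TriangleScene, face_slice: slice, cell: float) -> float:
    """Occupied-cell XY area of a face range, by dense triangle sampling."""
    faces = scene.faces[face_slice]
    cells = set()
    for f in faces:
        a, b, c = scene.vertices[f]
        max_edge = max(
            np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(a - c)
        )
        n = max(1, int(np.ceil(max_edge / (cell / 3.0))))
        ii, jj = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = ii + jj <= n
        u = ii[keep] / n
        v = jj[keep] / n
        pts = a + u[:, None] * (b - a) + v[:, None] * (c - a)
        keys = np.floor(pts[:, :2] / cell).astype(np.int64)
        cells.update(map(tuple, keys))
    return len(cells) * cell**2


# ---------------------------------------------------------------------------
# rendering


def _rasterize(
    verts_cam: np.ndarray,
    faces: np.ndarray,
    face_colors: np.ndarray,
    intr: CameraIntrinsics,
    near: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-shaded z-buffer rasterisation; returns (depth_m, rgb) images.

    Depth is +inf where nothing projects.  Triangles crossing the near
    plane are skipped (the scene never straddles the camera).
    """
    h, w = intr.height, intr.width
    depth = np.full((h, w), np.inf)
    rgb = np.zeros((h, w, 3))
    uv, z = intr.project(verts_cam)

    tz = z[faces]
    tu = uv[faces][:, :, 0]
    tv = uv[faces][:, :, 1]
    visible = (
        np.all(tz > near, axis=1)
        & (np.floor(tu.max(axis=1)) >= 0)
        & (np.ceil(tu.min(axis=1)) <= w - 1)
        & (np.floor(tv.max(axis=1)) >= 0)
        & (np.ceil(tv.min(axis=1)) <= h - 1)
    )
    for fi in np.nonzero(visible)[0]:
        u0, u1, u2 = tu[fi]
        v0, v1, v2 = tv[fi]
        z0, z1, z2 = tz[fi]
        umin = max(int(np.ceil(min(u0, u1, u2))), 0)
        umax = min(int(np.floor(max(u0, u1, u2))), w - 1)
        vmin = max(int(np.ceil(min(v0, v1, v2))), 0)
        vmax = min(int(np.floor(max(v0, v1, v2))), h - 1)
        if umin > umax or vmin > vmax:
            continue
        det = (u1 - u0) * (v2 - v0) - (u2 - u0) * (v1 - v0)
        if abs(det) < 1e-12:
            continue
        us = np.arange(umin, umax + 1)
        vs = np.arange(vmin, vmax + 1)
        UU, VV = np.meshgrid(us, vs, indexing="xy")
        du = UU - u0
        dv = VV - v0
        w1 = (du * (v2 - v0) - (u2 - u0) * dv) / det
        w2 = ((u1 - u0) * dv - du * (v1 - v0)) / det
        w0 = 1.0 - w1 - w2
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        inv_z = w0 / z0 + w1 / z1 + w2 / z2  # perspective-correct depth
        zpix = 1.0 / inv_z
        tile = depth[vmin : vmax + 1, umin : umax + 1]
        win = inside & (zpix < tile)
        if not win.any():
            continue
        tile[win] = zpix[win]
        rgb[vmin : vmax + 1, umin : umax + 1][win] = face_colors[fi]
    return depth, rgb


def _world_to_cam(points: np.ndarray, cam_center: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(points) - cam_center) @ CAM_TO_WORLD


def render_frame(
    scene: TriangleScene,
    cam_center,
    intr: CameraIntrinsics,
    index: int = 0,
    depth_noise_sigma: float = 0.001,
    pixel_noise: float = 2.0 / 255.0,
    rng: np.random.Generator | None = None,
    intr_depth: CameraIntrinsics | None = None,
    extr: CameraExtrinsics | None = None,
) -> RGBDFrame:
    """Render one RGB-D frame from a world camera position.

    By default depth and colour share the camera (aligned streams, as an
    SDK would deliver).  Passing ``intr_depth``/``extr`` renders the depth
    image from the offset depth camera instead, producing a misaligned
    pair for exercising the alignment chain.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cam_center = np.asarray(cam_center, dtype=float)
    verts_color = _world_to_cam(scene.vertices, cam_center)
    _, rgb = _rasterize(verts_color, scene.faces, scene.face_colors, intr)
    depth_cam_pts = verts_color
    intr_d = intr if intr_depth is None else intr_depth
    if extr is not None and not extr.is_identity:
        depth_cam_pts = extr.color_to_depth(verts_color)
    depth_m, _ = _rasterize(depth_cam_pts, scene.faces, scene.face_colors, intr_d)

    valid = np.isfinite(depth_m)
    noisy = np.where(
        valid, depth_m + rng.normal(0.0, depth_noise_sigma, depth_m.shape), 0.0
    )
    depth_units = np.clip(
        np.rint(noisy / intr_d.depth_scale), 0, np.iinfo(np.uint16).max
    ).astype(np.uint16)
    depth_units[~valid] = 0

    color8 = np.clip(
        rgb + rng.normal(0.0, pixel_noise, rgb.shape), 0.0, 1.0
    )
    color8 = np.rint(color8 * 255.0).astype(np.uint8)
    return RGBDFrame(
        index=index,
        depth=depth_units,
        color=color8,
        intr_depth=intr_d,
        intr_color=intr,
        extr=CameraExtrinsics.identity() if extr is None else extr,
    )


def render_sequence(
    scene: TriangleScene,
    track: CameraTrack,
    intr: CameraIntrinsics,
    depth_noise_sigma: float = 0.001,
    pixel_noise: float = 2.0 / 255.0,
    seed: int = 0,
    out_dir=None,
) -> tuple[list[RGBDFrame], np.ndarray]:
    """Render the full sweep; returns (frames, camera positions).

    Per-frame noise streams derive from (seed, frame index), so renders
    are reproducible frame by frame.  With ``out_dir`` the frames are also
    written as ``depth_####.png`` / ``color_####.png`` plus a
    ``camera.json`` spec, the layout :func:`canopyrecon.camera.load_frame`
    reads.
    """
    positions = track.positions()
    frames = []
    for k, c in enumerate(positions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        frames.append(
            render_frame(
                scene, c, intr, index=k,
                depth_noise_sigma=depth_noise_sigma,
                pixel_noise=pixel_noise, rng=rng,
            )
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spec = {
            "depth": intr.to_dict(),
            "color": intr.to_dict(),
            "extrinsics": CameraExtrinsics.identity().to_dict(),
        }
        (out / "camera.json").write_text(json.dumps(spec, indent=2))
        for f in frames:
            iio.imwrite(out / f"depth_{f.index:04d}.png", f.depth)
            iio.imwrite(out / f"color_{f.index:04d}.png", f.color)
    return frames, positions


# ---------------------------------------------------------------------------
# direct surface sampling (bypasses rendering)


def labeled_row_cloud(
    scene: TriangleScene, density: float, seed: int = 0, labels=None
) -> tuple[ColoredPointCloud, np.ndarray]:
    """Uniformly sample the scene surfaces with per-point plant labels.

    ``density`` is points per square metre; each face receives a Poisson
    draw with mean area*density, placed uniformly by barycentric sampling.
    ``labels`` restricts sampling to the given plant labels (e.g. ``[0]``
    for the first plant only).  Intended for unit-testing segmentation and
    traits in isolation.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    areas = scene.face_areas()
    if labels is not None:
        areas = np.where(np.isin(scene.face_labels, labels), areas, 0.0)
    counts = rng.poisson(areas * density)
    total = int(counts.sum())
    face_idx = np.repeat(np.arange(len(areas)), counts)
    r1 = np.sqrt(rng.random(total))
    r2 = rng.random(total)
    tri = scene.vertices[scene.faces[face_idx]]
    pts = (
        (1 - r1)[:, None] * tri[:, 0]
        + (r1 * (1 - r2))[:, None] * tri[:, 1]
        + (r1 * r2)[:, None] * tri[:, 2]
    )
    cloud = ColoredPointCloud(pts, scene.face_colors[face_idx])
    return cloud, scene.face_labels[face_idx].copy()
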