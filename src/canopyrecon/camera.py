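"""RGB-D camera model, frame I/O and depth/colour fusion.

An RGB-D sensor delivers a 16-bit depth image and an 8-bit colour image
per timestamp, each with its own pinhole intrinsics, plus the rigid
extrinsic transform taking depth-camera coordinates to colour-camera
coordinates.  This module aligns the two images (back-project, transform,
re-project) and fuses them into a :class:`~canopyrecon.cloud.ColoredPointCloud`.

Conventions: pixel coordinates are 0-based ``(u=column, v=row)``; depth is
stored as unsigned integers scaled by ``depth_scale`` (default 1 mm); depth
value 0 means "no measurement".  The sensor's stated working range,
0.11–1.5 m, bounds the default fusion depth window.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .cloud import ColoredPointCloud

__all__ = [
    "CameraIntrinsics",
    "CameraExtrinsics",
    "RGBDFrame",
    "load_frame",
    "load_camera_spec",
    "map_color_pixel_to_depth_pixel",
    "depth_for_color_pixels",
    "depth_map_for_color_image",
    "frame_to_pointcloud",
]

#: Realsense D435-class working range in metres.
DEPTH_MIN_DEFAULT = 0.11
DEPTH_MAX_DEFAULT = 1.5


@dataclass(frozen=True)
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    depth_scale: float = 0.001

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    def back_project(self, uv: np.ndarray, depth: np.ndarray) -> np.ndarray:
        """Pixels (N,2) + depths (N,) in metres -> camera-frame points (N,3)."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        z = np.asarray(depth, dtype=float)
        x = (uv[:, 0] - self.cx) * z / self.fx
        y = (uv[:, 1] - self.cy) * z / self.fy
        return np.column_stack([x, y, z])

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Camera-frame points (N,3) -> pixel coords (N,2) and depths (N,)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = pts[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.fx * pts[:, 0] / z + self.cx
            v = self.fy * pts[:, 1] / z + self.cy
        return np.column_stack([u, v]), z

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
            "depth_scale": self.depth_scale,
        }


@dataclass(frozen=True)
class CameraExtrinsics:
    """Rigid transform from depth-camera to colour-camera coordinates."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        T = np.asarray(self.T, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("R must be orthonormal with det(R) = +1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)

    @classmethod
    def identity(cls) -> "CameraExtrinsics":
        return cls(np.eye(3), np.zeros(3))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.R, np.eye(3), atol=1e-12) and np.allclose(
            self.T, 0.0, atol=1e-12
        )

    def depth_to_color(self, pts: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pts) @ self.R.T + self.T

    def color_to_depth(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.T) @ self.R

    def to_dict(self) -> dict:
        return {"R": self.R.reshape(-1).tolist(), "T": self.T.tolist()}


@dataclass
class RGBDFrame:
    """One timestamped depth + colour image pair with camera parameters."""

    index: int
    depth: np.ndarray
    color: np.ndarray
    intr_depth: CameraIntrinsics
    intr_color: CameraIntrinsics
    extr: CameraExtrinsics

    def __post_init__(self):
        d = np.asarray(self.depth)
        c = np.asarray(self.color)
        if d.shape != (self.intr_depth.height, self.intr_depth.width):
            raise ValueError(
                f"depth image {d.shape} does not match intrinsics "
                f"({self.intr_depth.height}, {self.intr_depth.width})"
            )
        if c.shape != (self.intr_color.height, self.intr_color.width, 3):
            raise ValueError(
                f"colour image {c.shape} does not match intrinsics "
                f"({self.intr_color.height}, {self.intr_color.width}, 3)"
            )
        if not np.issubdtype(d.dtype, np.integer):
            raise ValueError("depth image must hold integers (depth units)")
        if np.any(d < 0):
            raise ValueError("depth values must be non-negative")
        self.depth = d
        self.color = c

    @property
    def aligned(self) -> bool:
        """True when depth and colour share one camera (SDK-aligned streams)."""
        return (
            self.extr.is_identity
            and self.intr_depth.to_dict() == self.intr_color.to_dict()
        )


# ---------------------------------------------------------------------------
# frame I/O


def load_camera_spec(path) -> tuple[CameraIntrinsics, CameraIntrinsics, CameraExtrinsics]:
    with open(path) as fh:
        spec = json.load(fh)
    intr_d = CameraIntrinsics(**spec["depth"])
    intr_c = CameraIntrinsics(**spec["color"])
    ex = spec.get("extrinsics")
    extr = (
        CameraExtrinsics(np.asarray(ex["R"]).reshape(3, 3), ex["T"])
        if ex
        else CameraExtrinsics.identity()
    )
    return intr_d, intr_c, extr


def _index_from_name(path) -> int:
    m = re.findall(r"(\d+)", Path(path).stem)
    return int(m[-1]) if m else 0


def load_frame(depth_path, color_path, camera_spec) -> RGBDFrame:
    """Load one 16-bit depth PNG + 8-bit RGB PNG pair.

    The frame index is taken from the last run of digits in the depth file
    name.  A colour alpha channel, if present, is stripped.
    """
    for p in (depth_path, color_path, camera_spec):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    intr_d, intr_c, extr = load_camera_spec(camera_spec)
    depth = iio.imread(depth_path)
    if depth.ndim != 2:
        raise ValueError(f"{depth_path}: depth PNG must be single-channel")
    if depth.dtype != np.uint16:
        raise ValueError(
            f"{depth_path}: depth PNG must be 16-bit, got {depth.dtype}"
        )
    color = iio.imread(color_path)
    if color.ndim != 3 or color.shape[2] not in (3, 4):
        raise ValueError(f"{color_path}: colour PNG must be RGB or RGBA")
    if color.dtype != np.uint8:
        raise ValueError(f"{color_path}: colour PNG must be 8-bit")
    color = color[:, :, :3]
    return RGBDFrame(
        index=_index_from_name(depth_path),
        depth=depth,
        color=color,
        intr_depth=intr_d,
        intr_color=intr_c,
        extr=extr,
    )


# ---------------------------------------------------------------------------
# depth/colour alignment


def map_color_pixel_to_depth_pixel(p_rgb, depth_m: float, frame: RGBDFrame):
    """Map a colour pixel with candidate depth to its depth-image pixel.

    Back-projects the colour pixel at ``depth_m`` (metres), applies the
    inverse extrinsic transform and re-projects with the depth intrinsics.
    Returns fractional (u, v) in the depth image, or ``None`` when
    ``depth_m`` is non-positive (no measurement, hence no mapping).
    """
    if depth_m is None or not np.isfinite(depth_m) or depth_m <= 0:
        return None
    P_rgb = frame.intr_color.back_project(np.asarray(p_rgb, dtype=float), depth_m)
    P_ir = frame.extr.color_to_depth(P_rgb)
    uv, _ = frame.intr_depth.project(P_ir)
    return uv[0]


def _aligned_depth_image(frame: RGBDFrame) -> np.ndarray:
    """Depth resampled into the colour camera by forward projection.

    Every valid depth pixel is back-projected, moved through the
    extrinsics and splatted into the colour image with a z-buffer (nearest
    surface wins).  Returns metres, 0 where nothing projects.
    """
    intr_d, intr_c = frame.intr_depth, frame.intr_color
    vv, uu = np.nonzero(frame.depth > 0)
    if len(uu) == 0:
        return np.zeros((intr_c.height, intr_c.width))
    z = frame.depth[vv, uu].astype(float) * intr_d.depth_scale
    pts = intr_d.back_project(np.column_stack([uu, vv]).astype(float), z)
    pts_c = frame.extr.depth_to_color(pts)
    uv, zc = intr_c.project(pts_c)
    ui = np.rint(uv[:, 0]).astype(int)
    vi = np.rint(uv[:, 1]).astype(int)
    ok = (zc > 0) & (ui >= 0) & (ui < intr_c.width) & (vi >= 0) & (vi < intr_c.height)
    out = np.full((intr_c.height, intr_c.width), np.inf)
    np.minimum.at(out, (vi[ok], ui[ok]), zc[ok])
    out[~np.isfinite(out)] = 0.0
    return out


def depth_map_for_color_image(frame: RGBDFrame) -> np.ndarray:
    """Per-colour-pixel depth in metres (0 where missing).

    For aligned streams this is just the scaled depth image.  Otherwise the
    depth image is resampled by forward projection to get a candidate depth
    per colour pixel, the candidate seeds the colour->depth pixel mapping,
    and the depth actually stored at the mapped (nearest) depth pixel is
    returned; the mapping is iterated once with the read-back depth.
    """
    intr_d, intr_c = frame.intr_depth, frame.intr_color
    if frame.aligned:
        return frame.depth.astype(float) * intr_d.depth_scale

    cand = _aligned_depth_image(frame)
    v, u = np.nonzero(cand > 0)
    z = cand[v, u]
    uv_c = np.column_stack([u, v]).astype(float)
    out = np.zeros((intr_c.height, intr_c.width))

    for _ in range(2):  # candidate pass + one refinement with read-back depth
        P = intr_c.back_project(uv_c, z)
        uvd, _ = intr_d.project(frame.extr.color_to_depth(P))
        ui = np.rint(uvd[:, 0]).astype(int)
        vi = np.rint(uvd[:, 1]).astype(int)
        ok = (ui >= 0) & (ui < intr_d.width) & (vi >= 0) & (vi < intr_d.height)
        z_new = np.zeros_like(z)
        z_new[ok] = frame.depth[vi[ok], ui[ok]].astype(float) * intr_d.depth_scale
        alive = z_new > 0
        u, v, z = u[alive], v[alive], z_new[alive]
        uv_c = uv_c[alive]
    out[v, u] = z
    return out


def depth_for_color_pixels(frame: RGBDFrame, pixels) -> np.ndarray:
    """Depths in metres at the given colour pixels; NaN where missing.

    ``pixels`` is an (N, 2) array of (u, v) colour-pixel coordinates; a
    pixel outside the colour image bounds raises.
    """
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    ui = np.rint(px[:, 0]).astype(int)
    vi = np.rint(px[:, 1]).astype(int)
    if np.any(
        (ui < 0) | (ui >= frame.intr_color.width)
        | (vi < 0) | (vi >= frame.intr_color.height)
    ):
        raise ValueError("pixel outside colour image bounds")
    dm = depth_map_for_color_image(frame)
    z = dm[vi, ui]
    z = np.where(z > 0, z, np.nan)
    return z


def frame_to_pointcloud(
    frame: RGBDFrame,
    depth_min: float = DEPTH_MIN_DEFAULT,
    depth_max: float = DEPTH_MAX_DEFAULT,
) -> ColoredPointCloud:
    """Fuse one frame into a coloured cloud in colour-camera coordinates.

    One point per colour pixel whose mapped depth lies in
    ``[depth_min, depth_max]``; colours scaled to [0, 1].
    """
    if depth_min >= depth_max:
        raise ValueError("depth_min must be < depth_max")
    dm = depth_map_for_color_image(frame)
    vv, uu = np.nonzero((dm >= depth_min) & (dm <= depth_max))
    if len(uu) == 0:
        return ColoredPointCloud()
    z = dm[vv, uu]
    pts = frame.intr_color.back_project(np.column_stack([uu, vv]).astype(float), z)
    cols = frame.color[vv, uu].astype(float) / 255.0
    return ColoredPointCloud(pts, cols)
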