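"""Colored point clouds and PLY I/O.

:class:`ColoredPointCloud` is the currency of every stage after image
fusion: registration, filtering, segmentation and trait measurement all
consume and produce it.  Clouds are stored as plain float arrays (metres)
with per-point RGB in [0, 1].

PLY files are written binary little-endian with ``x,y,z`` float32 and
``red,green,blue`` uchar properties; the reader additionally accepts ascii
PLY and clouds without colour (points kept, colours defaulted to white).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform

__all__ = ["ColoredPointCloud", "read_ply", "write_ply"]


@dataclass
class ColoredPointCloud:
    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    colors: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        cols = np.asarray(self.colors, dtype=float).reshape(-1, 3)
        if len(cols) != len(pts):
            raise ValueError(
                f"points ({len(pts)}) and colors ({len(cols)}) row counts differ"
            )
        self.points = pts
        self.colors = np.clip(cols, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, T: RigidTransform) -> "ColoredPointCloud":
        """Affine image of the cloud under T; colours unchanged."""
        if len(self) == 0:
            return ColoredPointCloud(self.points.copy(), self.colors.copy())
        return ColoredPointCloud(T.apply(self.points), self.colors.copy())

    def select(self, mask_or_indices) -> "ColoredPointCloud":
        return ColoredPointCloud(
            self.points[mask_or_indices], self.colors[mask_or_indices]
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(mins, maxs) over the three axes; raises on empty cloud."""
        if len(self) == 0:
            raise ValueError("empty cloud has no bounds")
        return self.points.min(axis=0), self.points.max(axis=0)

    @classmethod
    def concatenate(cls, clouds) -> "ColoredPointCloud":
        clouds = list(clouds)
        if not clouds:
            return cls()
        return cls(
            np.vstack([c.points for c in clouds]),
            np.vstack([c.colors for c in clouds]),
        )


# ---------------------------------------------------------------------------
# PLY I/O


def write_ply(cloud: ColoredPointCloud, path) -> None:
    """Write a binary little-endian PLY with xyz float + rgb uchar."""
    n = len(cloud)
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "end_header\n"
    )
    xyz = cloud.points.astype("<f4")
    rgb = np.rint(cloud.colors * 255.0).clip(0, 255).astype(np.uint8)
    rec = np.empty(
        n,
        dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
               ("red", "u1"), ("green", "u1"), ("blue", "u1")],
    )
    rec["x"], rec["y"], rec["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    rec["red"], rec["green"], rec["blue"] = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())


_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def read_ply(path) -> ColoredPointCloud:
    """Read a PLY point cloud (ascii or binary little-endian).

    Requires x, y, z vertex properties; missing red/green/blue properties
    produce white points with a warning.
    """
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
                elif int(tokens[2]) > 0:
                    raise ValueError(
                        f"{path}: non-vertex element '{tokens[1]}' unsupported"
                    )
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError(f"{path}: list properties unsupported")
                props.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format '{fmt}'")
        if n_vertex is None:
            raise ValueError(f"{path}: no vertex element")
        names = [p[0] for p in props]
        for ax in ("x", "y", "z"):
            if ax not in names:
                raise ValueError(f"{path}: missing '{ax}' property")
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertex):
                rows.append(fh.readline().split())
            data = {}
            arr = (
                np.asarray(rows, dtype=float)
                if n_vertex
                else np.zeros((0, len(props)))
            )
            if arr.shape != (n_vertex, len(props)):
                raise ValueError(f"{path}: malformed ascii vertex data")
            for i, (name, _) in enumerate(props):
                data[name] = arr[:, i]
        else:
            dtype = np.dtype([(name, "<" + t) for name, t in props])
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise ValueError(f"{path}: truncated binary vertex data")
            rec = np.frombuffer(buf, dtype=dtype)
            data = {name: rec[name] for name, _ in props}

    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
    if all(c in data for c in ("red", "green", "blue")):
        cols = np.column_stack([data["red"], data["green"], data["blue"]])
        cols = cols.astype(float)
        # integer-typed colours are 8-bit; float colours assumed already [0,1]
        ctypes = dict(props)
        if not ctypes["red"].startswith("f"):
            cols = cols / 255.0
    else:
        warnings.warn(f"{path}: no colour properties; defaulting to white")
        cols = np.ones_like(points)
    return ColoredPointCloud(points, cols)
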