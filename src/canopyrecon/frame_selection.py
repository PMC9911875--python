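"""Feature-displacement frame selection for the moving platform.

The platform records at 30 Hz, so consecutive frames are nearly redundant.
Reconstruction uses only frames spaced a target metric distance apart.
The displacement between frames is estimated visually: scale-invariant
keypoints with 128-dim descriptors are matched between colour images by
Euclidean descriptor distance (matches kept below a 0.3 threshold on
unit-normalised descriptors), matches are restricted to the calibrated
working depth so one pixel-to-metre conversion coefficient *I* applies,
and the pixel offset of these homonymous points times *I* gives the metric
displacement.  A frame whose displacement from the last selected frame
reaches the configured range is selected, and the displacement also seeds
the coarse pure-translation registration matrix S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.color import rgb2gray
from skimage.feature import SIFT

from .camera import RGBDFrame, depth_for_color_pixels
from .geometry import RigidTransform

__all__ = [
    "ConversionCoefficient",
    "FeatureMatch",
    "FrameSelection",
    "TrackingLostError",
    "calibrate_conversion",
    "descriptor_distance",
    "match_features",
    "filter_matches_by_depth",
    "estimate_displacement",
    "select_frames",
    "build_coarse_transform",
]

DEFAULT_SPACING_RANGE = (0.05, 0.07)  # metres; >=60% overlap at 1.1 m height
DESCRIPTOR_DIM = 128


class TrackingLostError(RuntimeError):
    """Raised when too few feature matches survive to estimate motion."""


@dataclass(frozen=True)
class ConversionCoefficient:
    """Metres of real-world displacement per image pixel at ``calib_depth``."""

    I: float
    calib_depth: float

    def __post_init__(self):
        if self.I <= 0 or self.calib_depth <= 0:
            raise ValueError("I and calib_depth must be positive")


@dataclass
class FeatureMatch:
    ref_px: np.ndarray  # (u, v) in reference image
    obs_px: np.ndarray  # (u, v) in observation image
    dist: float  # descriptor Euclidean distance
    depth: float = np.nan  # metres at obs_px, NaN while unknown/missing

    def __post_init__(self):
        self.ref_px = np.asarray(self.ref_px, dtype=float).reshape(2)
        self.obs_px = np.asarray(self.obs_px, dtype=float).reshape(2)
        if self.dist < 0:
            raise ValueError("descriptor distance must be non-negative")


@dataclass
class FrameSelection:
    """Frames chosen for reconstruction plus their inter-frame displacements.

    ``displacements[k]`` is the (dx, dy) metric offset of selected frame k
    relative to the previously selected frame (the first entry is (0, 0)).
    """

    selected_indices: list[int]
    displacements: list[tuple[float, float]]
    overshoot_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        idx = list(self.selected_indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("selected indices must be strictly increasing")
        if len(self.displacements) != len(idx):
            raise ValueError("one displacement per selected frame required")

    def to_dict(self) -> dict:
        return {
            "selected_indices": list(self.selected_indices),
            "displacements": [list(map(float, d)) for d in self.displacements],
            "overshoot_indices": list(self.overshoot_indices),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSelection":
        return cls(
            selected_indices=[int(i) for i in d["selected_indices"]],
            displacements=[tuple(x) for x in d["displacements"]],
            overshoot_indices=[int(i) for i in d.get("overshoot_indices", [])],
        )


def calibrate_conversion(
    pixel_length: float, physical_length: float, depth: float
) -> ConversionCoefficient:
    """Conversion coefficient from a photographed scale plate.

    A plate of known ``physical_length`` (m) spanning ``pixel_length``
    pixels at working ``depth`` gives I = physical / pixels, i.e. Z/f for a
    pinhole camera.
    """
    if pixel_length <= 0 or physical_length <= 0 or depth <= 0:
        raise ValueError("calibration lengths and depth must be positive")
    return ConversionCoefficient(I=physical_length / pixel_length, calib_depth=depth)


def descriptor_distance(r: np.ndarray, c: np.ndarray) -> float:
    """Euclidean distance between two 128-dim feature descriptors."""
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    if r.shape != (DESCRIPTOR_DIM,) or c.shape != (DESCRIPTOR_DIM,):
        raise ValueError(f"descriptors must be {DESCRIPTOR_DIM}-vectors")
    return float(np.sqrt(np.sum((r - c) ** 2)))


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        return rgb2gray(img[:, :, :3])
    return img.astype(float) / 255.0 if img.dtype == np.uint8 else img


def detect_features(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale-invariant keypoints (N,2 as u,v) + unit-norm descriptors (N,128)."""
    sift = SIFT(upsampling=1)
    try:
        sift.detect_and_extract(_to_gray(image))
    except RuntimeError as exc:  # skimage raises when no keypoints found
        raise TrackingLostError(f"no keypoints detected: {exc}") from exc
    kp = sift.keypoints[:, ::-1].astype(float)  # (row, col) -> (u, v)
    desc = sift.descriptors.astype(float)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return kp, desc / norms


def match_features(
    ref_image: np.ndarray,
    obs_image: np.ndarray,
    dist_threshold: float = 0.3,
    min_matches: int = 8,
    ref_features: tuple[np.ndarray, np.ndarray] | None = None,
    obs_features: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[FeatureMatch]:
    """One-to-one descriptor matches with distance below the threshold.

    Descriptors are unit-normalised before thresholding so the 0.3 cut is
    scale-meaningful.  For each reference feature the nearest observation
    feature is taken; an observation feature claimed by several reference
    features keeps only its best (smallest-distance) pairing.

    Precomputed ``(keypoints, descriptors)`` pairs may be passed to avoid
    re-detecting a frame that is matched repeatedly.
    """
    if np.asarray(ref_image).shape != np.asarray(obs_image).shape:
        raise ValueError("reference and observation images must be same size")
    ref_kp, ref_desc = detect_features(ref_image) if ref_features is None else ref_features
    obs_kp, obs_desc = detect_features(obs_image) if obs_features is None else obs_features
    d = cdist(ref_desc, obs_desc)
    nearest = np.argmin(d, axis=1)
    ndist = d[np.arange(len(ref_desc)), nearest]
    keep = ndist < dist_threshold

    best_for_obs: dict[int, tuple[float, int]] = {}
    for i in np.nonzero(keep)[0]:
        j = int(nearest[i])
        if j not in best_for_obs or ndist[i] < best_for_obs[j][0]:
            best_for_obs[j] = (float(ndist[i]), int(i))
    matches = [
        FeatureMatch(ref_px=ref_kp[i], obs_px=obs_kp[j], dist=dist)
        for j, (dist, i) in sorted(best_for_obs.items())
    ]
    if len(matches) < min_matches:
        raise TrackingLostError(
            f"only {len(matches)} matches below {dist_threshold} "
            f"(minimum {min_matches}): tracking lost"
        )
    return matches


def filter_matches_by_depth(
    matches: list[FeatureMatch],
    frame: RGBDFrame,
    calib: ConversionCoefficient,
    rel_tol: float = 0.1,
) -> list[FeatureMatch]:
    """Keep matches whose depth sits at the calibrated working depth.

    The conversion coefficient is only valid at its calibration depth, so
    matches are restricted to ``|depth - calib_depth| <= rel_tol *
    calib_depth``; matches without a depth measurement are dropped.
    """
    if not matches:
        raise TrackingLostError("no matches to filter")
    px = np.array([m.obs_px for m in matches])
    depths = depth_for_color_pixels(frame, px)
    kept = []
    for m, z in zip(matches, depths):
        m.depth = float(z)
        if np.isfinite(z) and abs(z - calib.calib_depth) <= rel_tol * calib.calib_depth:
            kept.append(m)
    if not kept:
        raise TrackingLostError("no valid features at working depth")
    return kept


def estimate_displacement(
    matches: list[FeatureMatch], calib: ConversionCoefficient
) -> tuple[float, float]:
    """Metric (dx, dy) displacement from matched feature offsets.

    Component-wise median of (obs - ref) pixel offsets times *I*; the
    median resists residual mismatches.  dx is positive when scene content
    moves toward +u.
    """
    if not matches:
        raise ValueError("cannot estimate displacement from zero matches")
    offsets = np.array([m.obs_px - m.ref_px for m in matches])
    med = np.median(offsets, axis=0)
    return float(med[0] * calib.I), float(med[1] * calib.I)


def build_coarse_transform(dx: float, dy: float) -> RigidTransform:
    """Coarse registration matrix S for an estimated (dx, dy) displacement.

    S is the pure translation [[1,0,0,-dx],[0,1,0,-dy],[0,0,1,0],[0,0,0,1]]:
    applying it to the newly selected frame's cloud subtracts the platform
    displacement, bringing the cloud into the previous frame's coordinates.
    """
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("displacement must be finite")
    return RigidTransform.from_translation([-dx, -dy, 0.0])


class _FeatureDisplacement:
    """Default displacement estimator, caching the reference frame's features."""

    def __init__(self, calib, dist_threshold, rel_tol, min_matches):
        self.calib = calib
        self.dist_threshold = dist_threshold
        self.rel_tol = rel_tol
        self.min_matches = min_matches
        self._ref_index = None
        self._ref_features = None

    def __call__(self, ref_frame: RGBDFrame, frame: RGBDFrame):
        if self._ref_index != ref_frame.index:
            self._ref_features = detect_features(ref_frame.color)
            self._ref_index = ref_frame.index
        matches = match_features(
            ref_frame.color,
            frame.color,
            self.dist_threshold,
            self.min_matches,
            ref_features=self._ref_features,
        )
        matches = filter_matches_by_depth(matches, frame, self.calib, self.rel_tol)
        return estimate_displacement(matches, self.calib)


def select_frames(
    frames,
    calib: ConversionCoefficient,
    spacing_range: tuple[float, float] = DEFAULT_SPACING_RANGE,
    dist_threshold: float = 0.3,
    rel_tol: float = 0.1,
    min_matches: int = 8,
    displacement_fn=None,
) -> FrameSelection:
    """Select reconstruction frames spaced by metric displacement.

    The first frame is always selected.  Scanning forward, each frame is
    matched against the *last selected* frame (cumulative measurement, no
    per-step drift) and the first frame whose along-track distance |dx|
    reaches ``d_min`` is selected.  A frame that jumps straight past
    ``d_max`` is still selected but flagged as an overshoot (platform too
    fast for the configured range).

    ``displacement_fn(ref_frame, frame) -> (dx, dy)`` may replace the
    feature-based estimator (used for testing and simulation).
    """
    d_min, d_max = spacing_range
    if not d_min < d_max:
        raise ValueError("spacing range must satisfy d_min < d_max")
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame stream")
    if displacement_fn is None:
        displacement_fn = _FeatureDisplacement(
            calib, dist_threshold, rel_tol, min_matches
        )

    selected = [frames[0].index]
    displacements: list[tuple[float, float]] = [(0.0, 0.0)]
    overshoot: list[int] = []
    ref = frames[0]
    prev_dist = 0.0
    for fr in frames[1:]:
        dx, dy = displacement_fn(ref, fr)
        dist = abs(dx)
        if dist >= d_min:
            if dist > d_max and prev_dist < d_min:
                overshoot.append(fr.index)
                warnings.warn(
                    f"frame {fr.index}: displacement {dist:.3f} m overshot "
                    f"range [{d_min}, {d_max}] (platform too fast)"
                )
            selected.append(fr.index)
            displacements.append((dx, dy))
            ref = fr
            prev_dist = 0.0
        else:
            prev_dist = dist
    return FrameSelection(selected, displacements, overshoot)
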