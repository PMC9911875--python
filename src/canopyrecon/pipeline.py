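"""End-to-end pipeline orchestration with a run manifest.

One JSON config drives synth -> select -> reconstruct -> clean -> segment
-> traits; every stage writes its outputs under the configured work
directory and the manifest records per-stage parameters, point counts and
wall time.  The manifest is written even when a stage fails, marking the
failed stage.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cloud import write_ply
from .frame_selection import (
    DEFAULT_SPACING_RANGE,
    calibrate_conversion,
    select_frames,
)
from .geometry import RigidTransform, rotation_about_axis
from .preprocessing import FilterParams, clean_cloud
from .registration import RegistrationParams, reconstruct_row
from .segmentation import (
    SegmentationParams,
    color_segment,
    fit_ground_plane,
    level_cloud,
    segment_plants,
)
from .synthetic import (
    CameraTrack,
    SceneSpec,
    default_intrinsics,
    generate_scene,
    render_sequence,
)
from .traits import GridSpec, PlantRecord, plant_height, projected_area, trait_report

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full synthetic-to-traits run.

    Constructing the config validates every stage's parameter set (the
    nested dataclasses enforce their own invariants), so schema errors
    surface before any stage executes.
    """

    workdir: str
    seed: int = 0
    resolution: tuple = (424, 240)
    scene: SceneSpec = field(default_factory=SceneSpec)
    track: CameraTrack = field(default_factory=lambda: CameraTrack(speed=0.4, track_length=0.8))
    spacing_range: tuple = DEFAULT_SPACING_RANGE
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    filters: FilterParams = field(default_factory=FilterParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    grid_cell: float = 0.001

    def __post_init__(self):
        if self.grid_cell <= 0:
            raise ValueError("grid_cell must be positive")
        if not (len(self.resolution) == 2 and min(self.resolution) > 0):
            raise ValueError("resolution must be two positive integers")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = dict(raw)
        for key, typ in (
            ("scene", SceneSpec),
            ("track", CameraTrack),
            ("registration", RegistrationParams),
            ("filters", FilterParams),
            ("segmentation", SegmentationParams),
        ):
            if key in kwargs:
                sub = dict(kwargs[key])
                for k in list(sub):
                    if isinstance(sub[k], list):
                        sub[k] = tuple(sub[k])
                kwargs[key] = typ(**sub)
        for k in ("resolution", "spacing_range"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    status: str = "running"
    failed_stage: str | None = None
    error: str | None = None

    def record(self, name: str, started: float, **info):
        self.stages.append(
            {"stage": name, "wall_time_s": round(time.time() - started, 3), **info}
        )

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "status": self.status,
                    "failed_stage": self.failed_stage,
                    "error": self.error,
                    "config": self.config,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                default=str,
            )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; any failure halts with the manifest recording it."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    manifest_path = workdir / "manifest.json"

    stage = "synth"
    try:
        t0 = time.time()
        scene, gt = generate_scene(config.scene, projected_cell=config.grid_cell)
        intr = default_intrinsics(*config.resolution)
        frames, positions = render_sequence(
            scene,
            config.track,
            intr,
            depth_noise_sigma=config.scene.depth_noise_sigma,
            pixel_noise=config.scene.pixel_noise,
            seed=config.seed,
            out_dir=workdir / "frames",
        )
        (workdir / "ground_truth.json").write_text(json.dumps(gt.to_dict(), indent=2))
        manifest.record(stage, t0, n_frames=len(frames), out=str(workdir / "frames"))

        stage = "select"
        t0 = time.time()
        calib = calibrate_conversion(
            0.2 * intr.fx / config.track.height_above_ground,
            0.2,
            config.track.height_above_ground,
        )
        with warnings.catch_warnings(record=True) as wlog:
            warnings.simplefilter("always")
            selection = select_frames(frames, calib, config.spacing_range)
        (workdir / "selection.json").write_text(
            json.dumps(selection.to_dict(), indent=2)
        )
        manifest.record(
            stage, t0,
            n_selected=len(selection.selected_indices),
            warnings=[str(w.message) for w in wlog],
        )

        stage = "reconstruct"
        t0 = time.time()
        recon = reconstruct_row(frames, selection, config.registration)
        write_ply(recon.cloud, workdir / "row.ply")
        (workdir / "poses.json").write_text(
            json.dumps([p.M.tolist() for p in recon.poses], indent=2)
        )
        manifest.record(stage, t0, n_points=len(recon.cloud), out=str(workdir / "row.ply"))

        stage = "clean"
        t0 = time.time()
        cleaned = clean_cloud(recon.cloud, config.filters)
        write_ply(cleaned, workdir / "clean.ply")
        manifest.record(stage, t0, n_points=len(cleaned))

        stage = "segment"
        t0 = time.time()
        plane = fit_ground_plane(
            cleaned,
            dist_thresh=config.segmentation.ransac_dist,
            iters=config.segmentation.ransac_iters,
            seed=config.seed,
        )
        leveled, _ = level_cloud(cleaned, plane)
        plant_cloud, soil_cloud = color_segment(leveled)
        if len(plant_cloud) and np.median(plant_cloud.points[:, 2]) < 0:
            flip = RigidTransform.from_rotation_translation(
                rotation_about_axis([1.0, 0.0, 0.0], np.pi), [0, 0, 0]
            )
            plant_cloud = plant_cloud.transformed(flip)
            soil_cloud = soil_cloud.transformed(flip)
        plants, clusters = segment_plants(plant_cloud, config.segmentation)
        plants_dir = workdir / "plants"
        plants_dir.mkdir(exist_ok=True)
        for i, p in enumerate(plants):
            write_ply(p, plants_dir / f"plant_{i:03d}.ply")
        write_ply(soil_cloud, workdir / "soil.ply")
        (plants_dir / "manifest.json").write_text(
            json.dumps(
                [
                    {
                        "plant_id": i,
                        "n_points": len(p),
                        "mins": c.mins.tolist(),
                        "maxs": c.maxs.tolist(),
                    }
                    for i, (p, c) in enumerate(zip(plants, clusters))
                ],
                indent=2,
            )
        )
        manifest.record(stage, t0, n_plants=len(plants))

        stage = "traits"
        t0 = time.time()
        soil_plane = fit_ground_plane(
            soil_cloud,
            dist_thresh=config.segmentation.ransac_dist,
            iters=config.segmentation.ransac_iters,
            seed=config.seed + 1,
        )
        records = []
        for i, p in enumerate(plants):
            records.append(
                PlantRecord(
                    plant_id=i,
                    cloud=p,
                    height=plant_height(p, soil_plane),
                    projected_area=projected_area(p, GridSpec(config.grid_cell)),
                )
            )
        trait_report(records, workdir / "traits.csv")
        manifest.record(stage, t0, n_plants=len(records), out=str(workdir / "traits.csv"))
    except Exception as exc:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(manifest_path)
        raise
    manifest.status = "ok"
    manifest.write(manifest_path)
    return manifest
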