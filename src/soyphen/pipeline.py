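"""End-to-end workflow: raw scene cloud -> calibrated plant -> trait table.

Stage order follows the acquisition-to-traits workflow: ground detection
and alignment, metric calibration against the pot, voxel downsampling,
color background removal, statistical denoising, then the LPM trait
chain.  A :class:`PipelineConfig` (pydantic, unknown keys rejected) holds
every stage's parameters, and one global seed makes the whole run
reproducible — the same config and input produce byte-identical trait
tables.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import pc_io
from .cloud import PointCloud
from .geometry import (
    align_to_ground,
    apply_scale,
    compute_scale_factor,
    ransac_plane,
)
from .lpm import LPMConfig, TraitRecord, extract_all
from .preprocess import (
    color_background_filter,
    statistical_outlier_removal,
    voxel_downsample,
)
from .synth import BACKGROUND_COLOR_RANGES

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "measure_reference_length",
]


class CalibrationParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ref_real_length_cm: float = 27.0
    #: RGB box (min, max) selecting the reference-object (pot) points; the
    #: pot diameter is then the maximum horizontal extent of those points.
    ref_color_min: Tuple[int, int, int] = (150, 60, 30)
    ref_color_max: Tuple[int, int, int] = (230, 130, 95)
    ground_dist_threshold_frac: float = 0.004   # x scene bbox diagonal
    ransac_iterations: int = 400


class PreprocessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    voxel_size_cm: float = 0.12
    background_ranges: Tuple[
        Tuple[Tuple[int, int, int], Tuple[int, int, int]], ...
    ] = tuple(
        (tuple(lo), tuple(hi)) for lo, hi in BACKGROUND_COLOR_RANGES
    )
    sor_k: int = 8
    sor_n_sigma: float = 3.5


class LPMParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cluster_tol_cm: Optional[float] = None
    min_cluster_size: int = 60
    stem_dist_threshold_cm: float = 0.15
    stem_radius_min_cm: float = 0.05
    stem_radius_max_cm: float = 1.0
    stem_margin_cm: float = 0.3
    leaf_cell_size_cm: float = 0.2
    tilt_dist_threshold_cm: float = 0.5
    edge_cutoff: float = 4.0

    def to_lpm_config(self, seed: int) -> LPMConfig:
        return LPMConfig(
            cluster_tol=self.cluster_tol_cm,
            min_cluster_size=self.min_cluster_size,
            stem_dist_threshold=self.stem_dist_threshold_cm,
            stem_radius_bounds=(self.stem_radius_min_cm, self.stem_radius_max_cm),
            stem_margin=self.stem_margin_cm,
            leaf_cell_size=self.leaf_cell_size_cm,
            tilt_dist_threshold=self.tilt_dist_threshold_cm,
            edge_cutoff=self.edge_cutoff,
            seed=seed,
        )


class PipelineConfig(BaseModel):
    """Whole-workflow parameters; round-trips through JSON/YAML."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    calibration: CalibrationParams = CalibrationParams()
    preprocess: PreprocessParams = PreprocessParams()
    lpm: LPMParams = LPMParams()
    verbosity: int = 1


def measure_reference_length(
    aligned: PointCloud,
    color_min: Sequence[int],
    color_max: Sequence[int],
) -> float:
    """Pot diameter in raw units, from the reference-colored points of a
    ground-aligned cloud.

    The pot wall is a vertical cylinder, so its horizontal footprint is a
    circle: the diameter is estimated as twice the median radial distance
    of the pot-colored points from their horizontal centroid, which is
    robust to sensor noise (a max-extent estimate is biased upward by the
    noise tails).  Stands in for the interactive point-pair pick on real
    scans.
    """
    if not aligned.has_colors:
        raise ValueError("reference measurement needs a colored cloud")
    lo = np.asarray(color_min)
    hi = np.asarray(color_max)
    cols = aligned.colors.astype(np.int64)
    mask = ((cols >= lo) & (cols <= hi)).all(axis=1)
    if mask.sum() < 10:
        raise ValueError("too few reference-colored points to measure the pot")
    xy = aligned.points[mask, :2]
    radial = np.linalg.norm(xy - xy.mean(axis=0), axis=1)
    return float(2.0 * np.median(radial))


def run_pipeline(
    cloud: PointCloud,
    config: Optional[PipelineConfig] = None,
    plant_id: str = "plant",
) -> Tuple[TraitRecord, dict]:
    """Run ground alignment, calibration, preprocessing and the LPM chain.

    Returns the trait record and a JSON-serialisable log with per-stage
    point counts and the calibration/alignment summary.
    """
    config = config or PipelineConfig()
    log: dict = {"stages": [], "seed": config.seed}

    def note(stage, n, **extra):
        entry = {"stage": stage, "points": int(n), **extra}
        log["stages"].append(entry)

    note("input", len(cloud))

    # 1. ground detection + alignment (raw units; adaptive threshold)
    diag = float(np.linalg.norm(cloud.points.max(axis=0) - cloud.points.min(axis=0)))
    thresh = config.calibration.ground_dist_threshold_frac * diag
    ground = ransac_plane(
        cloud,
        dist_threshold=thresh,
        max_iterations=config.calibration.ransac_iterations,
        seed=config.seed,
    )
    aligned, (rot, translation) = align_to_ground(cloud, ground, return_transform=True)
    note(
        "align_to_ground",
        len(aligned),
        rotation_deg=float(np.degrees(rot.angle)),
        ground_inliers=int(len(ground.inlier_indices)),
    )

    # 2. metric calibration against the pot
    measured = measure_reference_length(
        aligned,
        config.calibration.ref_color_min,
        config.calibration.ref_color_max,
    )
    cal = compute_scale_factor(measured, config.calibration.ref_real_length_cm)
    cloud_cm = apply_scale(aligned, cal)
    note("apply_scale", len(cloud_cm), alpha=cal.alpha, measured_raw=measured)

    # 3. preprocessing (cm units)
    pp = config.preprocess
    cloud_cm = voxel_downsample(cloud_cm, pp.voxel_size_cm)
    note("voxel_downsample", len(cloud_cm))
    plant = color_background_filter(cloud_cm, pp.background_ranges)
    note("color_background_filter", len(plant))
    if len(plant) > pp.sor_k + 1:
        plant = statistical_outlier_removal(plant, pp.sor_k, pp.sor_n_sigma)
    note("statistical_outlier_removal", len(plant))

    # 4. traits
    record = extract_all(
        plant, config.lpm.to_lpm_config(config.seed), plant_id=plant_id
    )
    note("extract_all", len(plant), leaf_count=record.leaf_count)
    return record, log


def run_to_files(
    cloud: PointCloud,
    out_dir: str,
    config: Optional[PipelineConfig] = None,
    plant_id: str = "plant",
) -> Tuple[TraitRecord, dict]:
    """Run the pipeline and write traits.csv + manifest.json to a run dir."""
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    record, log = run_pipeline(cloud, config, plant_id=plant_id)
    csv_path = os.path.join(out_dir, "traits.csv")
    pc_io.write_trait_table([record], csv_path)
    log["config"] = json.loads(config.model_dump_json())
    log["outputs"] = {"traits_csv": csv_path}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return record, log
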