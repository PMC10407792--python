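"""Metric calibration and ground alignment.

An SfM reconstruction is only defined up to a similarity transform, so two
steps anchor it to the physical plant:

1. *Scale calibration* against a reference object of known size (here the
   pot): the ratio ``alpha = real_length_cm / measured_length_raw``
   multiplies every coordinate, converting the cloud to centimetres.
2. *Ground alignment*: the dominant plane found by RANSAC is taken as the
   ground; the rotation that maps its normal onto +z (built with the
   axis-angle Rodrigues formula) is applied, followed by a translation
   putting the ground inliers at z = 0.  After this the plant grows along
   +z, which the trait extractor assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .cloud import PointCloud

__all__ = [
    "CalibrationResult",
    "PlaneModel",
    "RotationSpec",
    "compute_scale_factor",
    "apply_scale",
    "ransac_plane",
    "rodrigues_rotation",
    "align_to_ground",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Scale factor mapping raw reconstruction units to centimetres."""

    alpha: float
    measured_length: float
    real_length: float


@dataclass
class PlaneModel:
    """Plane ``normal . p + offset = 0`` with unit normal, its RANSAC/LS
    inliers, the inlier RMSE and the distance threshold it was fit with."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray
    rmse: float
    dist_threshold: float = float("nan")

    def distances(self, points: np.ndarray) -> np.ndarray:
        """Signed orthogonal distances of ``points`` to the plane."""
        return points @ self.normal + self.offset


@dataclass(frozen=True)
class RotationSpec:
    """Axis-angle rotation taking direction ``source`` onto ``target``."""

    source: np.ndarray
    target: np.ndarray
    angle: float            # radians
    axis: np.ndarray        # unit rotation axis
    matrix: np.ndarray      # 3x3 proper rotation


def compute_scale_factor(measured_length: float, real_length: float) -> CalibrationResult:
    """``alpha = real_length / measured_length`` (both strictly positive)."""
    if measured_length <= 0 or real_length <= 0:
        raise ValueError("reference lengths must be > 0")
    return CalibrationResult(
        alpha=real_length / measured_length,
        measured_length=measured_length,
        real_length=real_length,
    )


def apply_scale(pc: PointCloud, cal: CalibrationResult) -> PointCloud:
    """Multiply every coordinate by ``cal.alpha`` and flip the unit to cm.

    Refuses to run twice: a cloud already in cm must not be rescaled.
    """
    if pc.unit == "cm":
        raise ValueError("cloud is already calibrated to cm; refusing to rescale")
    return PointCloud(pc.points * cal.alpha, pc.colors, unit="cm")


def _fit_plane_lsq(points: np.ndarray) -> Tuple[np.ndarray, float]:
    """Total-least-squares plane through ``points``: unit normal + offset."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(points) < 3 or (len(s) > 1 and s[1] < 1e-12 * max(s[0], 1.0)):
        raise ValueError("degenerate (collinear) points: plane undefined")
    normal = vt[-1]
    return normal, float(-normal @ centroid)


def ransac_plane(
    pc: PointCloud,
    dist_threshold: float,
    max_iterations: int = 500,
    seed: int = 0,
) -> PlaneModel:
    """RANSAC plane: maximise the inlier count over random 3-point
    hypotheses, then refine by total least squares on the final inliers.

    Deterministic for a given ``seed``.  The refined plane's inlier set is
    re-evaluated so every reported inlier is within ``dist_threshold``.
    """
    pts = pc.points if isinstance(pc, PointCloud) else np.asarray(pc, float)
    n = len(pts)
    if n < 3:
        raise ValueError(f"need >= 3 points to fit a plane, got {n}")
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be > 0")
    rng = np.random.default_rng(seed)
    best_count = -1
    best_normal = None
    best_offset = 0.0
    for _ in range(max_iterations):
        i, j, k = rng.choice(n, size=3, replace=False)
        v1 = pts[j] - pts[i]
        v2 = pts[k] - pts[i]
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue  # collinear sample
        normal = normal / norm
        offset = -float(normal @ pts[i])
        count = int(np.count_nonzero(np.abs(pts @ normal + offset) <= dist_threshold))
        if count > best_count:
            best_count = count
            best_normal, best_offset = normal, offset
    if best_normal is None:
        raise ValueError("all RANSAC samples were collinear; cannot fit a plane")
    # refine: LS on inliers, re-select inliers, refine once more
    for _ in range(2):
        mask = np.abs(pts @ best_normal + best_offset) <= dist_threshold
        if np.count_nonzero(mask) < 3:
            break
        try:
            best_normal, best_offset = _fit_plane_lsq(pts[mask])
        except ValueError:
            break
    inliers = np.flatnonzero(np.abs(pts @ best_normal + best_offset) <= dist_threshold)
    resid = pts[inliers] @ best_normal + best_offset
    rmse = float(np.sqrt(np.mean(resid**2))) if len(inliers) else float("nan")
    return PlaneModel(
        normal=best_normal,
        offset=float(best_offset),
        inlier_indices=inliers,
        rmse=rmse,
        dist_threshold=dist_threshold,
    )


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def rodrigues_rotation(m, n=(0.0, 0.0, 1.0)) -> RotationSpec:
    """Rotation taking the direction of ``m`` onto the direction of ``n``.

    The rotation angle is ``arccos(m.n / |m||n|)`` and the axis is the
    normalised cross product; the matrix is the axis-angle Rodrigues form
    ``R = cos(t) I + (1 - cos(t)) d d^T + sin(t) [d]_x``.  Parallel inputs
    yield the identity; antiparallel inputs rotate 180 degrees about a
    deterministic axis orthogonal to ``m`` (the coordinate axis least
    aligned with ``m``, orthogonalised).
    """
    m = np.asarray(m, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    nm = np.linalg.norm(m)
    nn = np.linalg.norm(n)
    if nm == 0 or nn == 0:
        raise ValueError("m and n must be non-zero vectors")
    mu = m / nm
    nu = n / nn
    c = float(np.clip(mu @ nu, -1.0, 1.0))
    theta = float(np.arccos(c))
    cross = np.cross(mu, nu)
    s = np.linalg.norm(cross)
    if s < 1e-12:
        if c > 0:  # parallel
            return RotationSpec(mu, nu, 0.0, np.array([0.0, 0.0, 1.0]), np.eye(3))
        # antiparallel: 180 deg about a deterministic orthogonal axis
        pick = np.argmin(np.abs(mu))
        helper = np.zeros(3)
        helper[pick] = 1.0
        axis = helper - (helper @ mu) * mu
        axis /= np.linalg.norm(axis)
        theta = np.pi
    else:
        axis = cross / s
    ct, st = np.cos(theta), np.sin(theta)
    R = ct * np.eye(3) + (1.0 - ct) * np.outer(axis, axis) + st * _skew(axis)
    return RotationSpec(mu, nu, theta, axis, R)


def align_to_ground(
    pc: PointCloud,
    ground: PlaneModel,
    return_transform: bool = False,
):
    """Rotate the cloud so the ground normal becomes +z, then translate so
    the ground inliers' mean sits at z = 0.

    The ground normal is first oriented toward the cloud's centroid (the
    plant sits above the ground), so "up" is well defined.  Returns the
    aligned cloud, plus ``(RotationSpec, translation)`` when
    ``return_transform`` is true.
    """
    pts = pc.points
    normal = ground.normal.copy()
    offset = ground.offset
    centroid = pts.mean(axis=0)
    if normal @ centroid + offset < 0:
        normal, offset = -normal, -offset
    rot = rodrigues_rotation(normal, (0.0, 0.0, 1.0))
    rotated = pts @ rot.matrix.T
    if len(ground.inlier_indices):
        z0 = rotated[ground.inlier_indices, 2].mean()
    else:
        z0 = rotated[:, 2].min()
    translation = np.array([0.0, 0.0, -z0])
    aligned = pc.with_points(rotated + translation)
    if return_transform:
        return aligned, (rot, translation)
    return aligned
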