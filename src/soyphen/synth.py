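"""Synthetic pot-grown soybean scenes with exact ground truth.

Real reconstruction clouds come with no reference measurements attached,
so every pipeline stage here is validated against generated scenes whose
trait values are known by construction: a ground plane, a cylindrical pot
of known diameter (the metric reference), a vertical stem, and N curved
elliptical leaflets with per-leaf length, width, tilt and curvature, plus
sensor noise and dark background clutter.  Leaves are single elliptical
laminae kept apart by a minimum clearance, so the gap assumption behind
Euclidean leaf clustering holds by construction.

The assembled scene is handed out in "raw" units: a hidden uniform scale,
a random rigid tilt and a translation are applied, so the calibration and
ground-alignment stages are exercised nontrivially.  The truth manifest
stays in the aligned cm frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cloud import PointCloud
from .classify import FEATURE_NAMES, TraitMatrix

__all__ = [
    "LeafSpec",
    "SyntheticPlantSpec",
    "LeafTruth",
    "SyntheticTruth",
    "make_leaf",
    "make_plant",
    "make_trait_dataset",
    "BACKGROUND_COLOR_RANGES",
]

# RGB boxes covering the non-plant scene elements (pot, soil, and the dark
# fleece ground/clutter); greens stay well outside these boxes.
BACKGROUND_COLOR_RANGES = [
    ((80, 40, 0), (230, 130, 95)),     # soil browns / terracotta pot
    ((0, 0, 0), (45, 45, 45)),         # dark fleece ground and clutter
]

_GROUND_COLOR = (30, 30, 30)           # black fleece on the turntable
_POT_COLOR = (190, 90, 60)             # terracotta: the metric reference
_SOIL_COLOR = (110, 70, 40)
_STEM_COLOR = (80, 150, 60)
_LEAF_COLOR = (60, 170, 70)
_CLUTTER_COLOR = (15, 15, 15)


@dataclass
class LeafSpec:
    """One elliptical leaflet: size (cm), pose and bend."""

    length: float
    width: float
    attach_height: float        # cm above the soil surface
    azimuth_deg: float
    tilt_deg: float
    curvature: float = 0.01     # 1/cm, parabolic bend along the main axis


@dataclass
class SyntheticPlantSpec:
    """Scene description; defaults emulate a pot-grown R4-stage plant."""

    stem_height: float = 24.0
    stem_radius: float = 0.3
    pot_diameter: float = 27.0
    pot_height: float = 21.0
    leaves: Optional[List[LeafSpec]] = None
    n_leaves: int = 5
    density: float = 100.0          # points / cm^2 on plant surfaces
    noise_sd: float = 0.05          # cm
    n_clutter: int = 250
    clearance: float = 1.2          # min gap between leaves / stem (cm)
    scene_tilt_deg: float = 20.0    # rigid tilt applied to the raw scene
    seed: int = 0


@dataclass
class LeafTruth:
    length_cm: float
    width_cm: float
    tilt_deg: float
    projection_area_cm2: float
    projection_length_cm: float
    projection_width_cm: float
    aabb_volume_cm3: float
    shell_volume_cm3: float
    cell_size_cm: float
    center_cm: Tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class SyntheticTruth:
    height_cm: float
    aabb_volume_cm3: float
    leaf_count: int
    leaves: List[LeafTruth]
    pot_diameter_cm: float
    scale_alpha: float              # hidden cm-per-raw-unit factor
    background_color_ranges: tuple = tuple(BACKGROUND_COLOR_RANGES)


# ---------------------------------------------------------------------------
# leaf surface machinery

def _leaf_rotation(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """World rotation of the local leaf frame: tilt about the width axis,
    then azimuth about z."""
    t = np.deg2rad(tilt_deg)
    a = np.deg2rad(azimuth_deg)
    R_tilt = np.array(
        [[np.cos(t), 0.0, -np.sin(t)], [0.0, 1.0, 0.0], [np.sin(t), 0.0, np.cos(t)]]
    )
    R_az = np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    return R_az @ R_tilt


def _sample_ellipse(
    length: float, width: float, density: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform (u, v) samples inside the ellipse (2u/L)^2 + (2v/W)^2 <= 1."""
    area = np.pi * (length / 2.0) * (width / 2.0)
    n = max(int(round(density * area)), 16)
    # sample uniformly on the unit disk, then stretch
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    u = r * np.cos(th) * (length / 2.0)
    v = r * np.sin(th) * (width / 2.0)
    return u, v


def _ellipse_grid(length: float, width: float, m: int = 160):
    """Deterministic quadrature grid over the ellipse (masked rectangle)."""
    us = np.linspace(-length / 2.0, length / 2.0, m)
    vs = np.linspace(-width / 2.0, width / 2.0, m)
    du = us[1] - us[0]
    dv = vs[1] - vs[0]
    U, V = np.meshgrid(us, vs, indexing="ij")
    mask = (2 * U / length) ** 2 + (2 * V / width) ** 2 <= 1.0
    return U[mask], V[mask], du * dv


def _leaf_truth(
    spec: LeafSpec,
    cell_size: float = 0.2,
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LeafTruth:
    """Trait truth for a noiseless leaf, by quadrature over the surface."""
    R = _leaf_rotation(spec.tilt_deg, spec.azimuth_deg)
    U, V, dA = _ellipse_grid(spec.length, spec.width)
    # projected area: |det d(x,y)/d(u,v)| integrated over the ellipse
    du_vec = np.stack(
        [np.full_like(U, R[0, 0]) + R[0, 2] * 2 * spec.curvature * U,
         np.full_like(U, R[1, 0]) + R[1, 2] * 2 * spec.curvature * U],
        axis=-1,
    )
    dv_vec = np.array([R[0, 1], R[1, 1]])
    det = du_vec[..., 0] * dv_vec[1] - du_vec[..., 1] * dv_vec[0]
    proj_area = float(np.abs(det).sum() * dA)
    # dense noiseless surface points for extent / box / shell truths
    pts = np.stack([U, V, spec.curvature * U**2], axis=-1) @ R.T
    xy = pts[:, :2]
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, np.argsort(evals)[::-1]]
    proj = centered @ axes
    ext = proj.max(axis=0) - proj.min(axis=0)
    # full-PCA bounding box of the 3D surface
    c3 = pts - pts.mean(axis=0)
    cov3 = c3.T @ c3 / len(c3)
    evals3, evecs3 = np.linalg.eigh(cov3)
    p3 = c3 @ evecs3
    ext3 = p3.max(axis=0) - p3.min(axis=0)
    # shell volume at the stated cell size: occupancy needs a much denser
    # surface sampling than the extent/area quadrature to saturate every
    # cell the continuous surface touches
    Us, Vs, _ = _ellipse_grid(spec.length, spec.width, m=640)
    dense = np.stack([Us, Vs, spec.curvature * Us**2], axis=-1) @ R.T
    vox = np.floor((dense - dense.min(axis=0)) / cell_size).astype(np.int64)
    shell = len(np.unique(vox, axis=0)) * cell_size**3
    world_center = tuple(np.asarray(center, float) + pts.mean(axis=0))
    return LeafTruth(
        length_cm=spec.length,
        width_cm=spec.width,
        tilt_deg=spec.tilt_deg,
        projection_area_cm2=proj_area,
        projection_length_cm=float(ext[0]),
        projection_width_cm=float(ext[1]),
        aabb_volume_cm3=float(np.prod(ext3)),
        shell_volume_cm3=float(shell),
        cell_size_cm=cell_size,
        center_cm=world_center,
    )


def make_leaf(
    length: float,
    width: float,
    tilt_deg: float = 0.0,
    curvature: float = 0.0,
    density: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    azimuth_deg: float = 0.0,
) -> Tuple[np.ndarray, LeafTruth]:
    """Sample one leaf surface (points centred at the origin) plus truth.

    Deterministic given ``seed``.
    """
    if length <= 0 or width <= 0:
        raise ValueError("leaf dimensions must be > 0")
    rng = np.random.default_rng(seed)
    u, v = _sample_ellipse(length, width, density, rng)
    local = np.stack([u, v, curvature * u**2], axis=-1)
    R = _leaf_rotation(tilt_deg, azimuth_deg)
    pts = local @ R.T
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    spec = LeafSpec(length, width, 0.0, azimuth_deg, tilt_deg, curvature)
    return pts, _leaf_truth(spec)


# ---------------------------------------------------------------------------
# scene assembly

def _cylinder_shell(radius, z0, z1, density, rng):
    area = 2 * np.pi * radius * (z1 - z0)
    n = max(int(round(density * area)), 32)
    th = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(z0, z1, n)
    return np.stack([radius * np.cos(th), radius * np.sin(th), z], axis=-1)


def _disk(radius, z, density, rng, r_min=0.0):
    area = np.pi * (radius**2 - r_min**2)
    n = max(int(round(density * area)), 32)
    r = np.sqrt(rng.uniform(r_min**2, radius**2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.stack([r * np.cos(th), r * np.sin(th), np.full(n, float(z))], axis=-1)


def _default_leaves(
    spec: SyntheticPlantSpec, rng: np.random.Generator
) -> List[LeafSpec]:
    """Place ``n_leaves`` leaves with enforced azimuth/height separation."""
    n = spec.n_leaves
    leaves: List[LeafSpec] = []
    if n == 0:
        return leaves
    z_lo = 0.35 * spec.stem_height
    z_hi = 0.95 * spec.stem_height
    heights = np.linspace(z_lo, z_hi, n)
    base_az = rng.uniform(0, 360)
    golden = 137.5
    for i in range(n):
        leaves.append(
            LeafSpec(
                length=float(rng.uniform(8.0, 11.0)),
                width=float(rng.uniform(3.5, 5.0)),
                attach_height=float(heights[i]),
                azimuth_deg=float((base_az + golden * i) % 360.0),
                tilt_deg=float(rng.uniform(10.0, 40.0)),
                curvature=float(rng.uniform(0.005, 0.015)),
            )
        )
    return leaves


def _min_set_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    return float(cKDTree(a).query(b, k=1)[0].min())


def make_plant(
    spec: Optional[SyntheticPlantSpec] = None,
) -> Tuple[PointCloud, SyntheticTruth]:
    """Assemble a full colored scene in raw units + its truth manifest.

    The scene contains ground, pot (the metric reference), soil, stem,
    leaves and clutter; a hidden uniform scale in [0.5, 2], a rigid tilt of
    up to ``scene_tilt_deg`` and a translation map the cm frame to raw
    units.  Raises when the leaf clearance cannot be satisfied.
    """
    spec = spec or SyntheticPlantSpec()
    rng = np.random.default_rng(spec.seed)
    soil_z = spec.pot_height
    pot_r = spec.pot_diameter / 2.0

    leaves_spec = spec.leaves if spec.leaves is not None else _default_leaves(spec, rng)

    parts: List[np.ndarray] = []
    colors: List[np.ndarray] = []

    def add(pts, color, jitter=10):
        parts.append(pts)
        base = np.asarray(color, float)
        c = base + rng.integers(-jitter, jitter + 1, size=(len(pts), 3))
        colors.append(np.clip(c, 0, 255).astype(np.uint8))

    # background surfaces only need enough points for robust plane fits
    # and the pot-diameter measurement; plant surfaces carry full density
    ground_r = max(2.2 * pot_r, 30.0)
    add(_disk(ground_r, 0.0, spec.density * 0.12, rng, r_min=pot_r), _GROUND_COLOR)
    add(_cylinder_shell(pot_r, 0.0, soil_z, spec.density * 0.15, rng), _POT_COLOR)
    add(_disk(pot_r, soil_z, spec.density * 0.12, rng, r_min=spec.stem_radius), _SOIL_COLOR)
    stem_pts = _cylinder_shell(
        spec.stem_radius, soil_z, soil_z + spec.stem_height, spec.density * 1.2, rng
    )
    add(stem_pts, _STEM_COLOR)

    leaf_clouds: List[np.ndarray] = []
    leaf_truths: List[LeafTruth] = []
    for i, lf in enumerate(leaves_spec):
        placed = None
        az = lf.azimuth_deg
        for attempt in range(24):
            R = _leaf_rotation(lf.tilt_deg, az)
            u, v = _sample_ellipse(lf.length, lf.width, spec.density, rng)
            local = np.stack([u, v, lf.curvature * u**2], axis=-1)
            pts = local @ R.T
            # radial offset so the inner tip clears the stem
            reach_in = (lf.length / 2.0) * np.cos(np.deg2rad(lf.tilt_deg))
            r_c = spec.stem_radius + spec.clearance + reach_in
            center = np.array(
                [
                    r_c * np.cos(np.deg2rad(az)),
                    r_c * np.sin(np.deg2rad(az)),
                    soil_z + lf.attach_height,
                ]
            )
            pts = pts + center
            ok = _min_set_distance(stem_pts, pts) >= spec.clearance * 0.75
            if ok:
                for other in leaf_clouds:
                    if _min_set_distance(other, pts) < spec.clearance:
                        ok = False
                        break
            if ok:
                placed = (pts, az)
                break
            az = float((az + rng.uniform(30.0, 90.0)) % 360.0)
        if placed is None:
            raise ValueError(
                f"could not place leaf {i} with clearance {spec.clearance} cm; "
                "reduce n_leaves or the leaf sizes"
            )
        pts, az = placed
        leaf_clouds.append(pts)
        truth_spec = LeafSpec(
            lf.length, lf.width, lf.attach_height, az, lf.tilt_deg, lf.curvature
        )
        leaf_truths.append(_leaf_truth(truth_spec, center=tuple(center)))
        add(pts, _LEAF_COLOR)

    # plant-level truth from the noiseless plant geometry (stem + leaves)
    plant_pts = np.vstack([stem_pts] + leaf_clouds)
    height = float(plant_pts[:, 2].max())
    xy = plant_pts[:, :2] - plant_pts[:, :2].mean(axis=0)
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, np.argsort(evals)[::-1]]
    pxy = xy @ axes
    ext_xy = pxy.max(axis=0) - pxy.min(axis=0)
    ext_z = plant_pts[:, 2].max() - plant_pts[:, 2].min()
    aabb = float(ext_xy[0] * ext_xy[1] * ext_z)

    # clutter: dark fleece points scattered around the scene
    if spec.n_clutter > 0:
        lo = np.array([-ground_r, -ground_r, 0.0])
        hi = np.array([ground_r, ground_r, soil_z + spec.stem_height + 10.0])
        clutter = rng.uniform(lo, hi, size=(spec.n_clutter, 3))
        add(clutter, _CLUTTER_COLOR, jitter=5)

    pts = np.vstack(parts)
    cols = np.vstack(colors)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, pts.shape)

    # hidden similarity transform: cm -> raw units
    alpha = float(rng.uniform(0.5, 2.0))
    tilt = np.deg2rad(rng.uniform(0.0, spec.scene_tilt_deg))
    az = rng.uniform(0.0, 2 * np.pi)
    axis = np.array([np.cos(az), np.sin(az), 0.0])
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    R_scene = np.eye(3) + np.sin(tilt) * K + (1 - np.cos(tilt)) * (K @ K)
    t_scene = rng.uniform(-5.0, 5.0, 3)
    raw = (pts @ R_scene.T + t_scene) / alpha

    truth = SyntheticTruth(
        height_cm=height,
        aabb_volume_cm3=aabb,
        leaf_count=len(leaf_truths),
        leaves=leaf_truths,
        pot_diameter_cm=spec.pot_diameter,
        scale_alpha=alpha,
    )
    return PointCloud(raw, cols, unit="raw"), truth


# ---------------------------------------------------------------------------
# trait dataset for the classifiers

#: geometric means of the six leaf traits for the reference cultivar
_BASE_TRAITS = {
    "leaf_aabb_volume_cm3": 15.0,
    "leaf_volume_cm3": 3.0,
    "projection_length_cm": 9.0,
    "projection_width_cm": 4.5,
    "projection_area_cm2": 30.0,
    "tilt_angle_deg": 25.0,
}

#: exponent of the linear-dimension multiplier per trait (area ~ s^2 ...)
_DIMENSION_EXPONENT = {
    "leaf_aabb_volume_cm3": 3.0,
    "leaf_volume_cm3": 3.0,
    "projection_length_cm": 1.0,
    "projection_width_cm": 1.0,
    "projection_area_cm2": 2.0,
    "tilt_angle_deg": 0.0,
}


def make_trait_dataset(
    n_per_class: int = 149,
    class_shifts: Sequence[float] = (0.8, 1.0, 1.25),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> TraitMatrix:
    """Per-leaf six-trait samples from class-shifted lognormal draws.

    Each class ``c`` multiplies every linear leaf dimension by
    ``class_shifts[c]`` (areas and volumes scale with the square and cube),
    emulating the small/medium/large cultivar contrast; ``noise_sd`` is the
    within-class log-scale spread.  With the defaults, adjacent classes are
    separated by >= 3 within-class standard deviations on the volumetric
    traits.  Labels are integers 1..C.  Deterministic given ``seed``.
    """
    if len(class_shifts) < 2:
        raise ValueError("need >= 2 classes")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for ci, shift in enumerate(class_shifts, start=1):
        z = rng.normal(0.0, 1.0, size=(n_per_class, len(FEATURE_NAMES)))
        feats = np.empty_like(z)
        for fj, name in enumerate(FEATURE_NAMES):
            mean = _BASE_TRAITS[name] * shift ** _DIMENSION_EXPONENT[name]
            feats[:, fj] = mean * np.exp(noise_sd * z[:, fj])
        rows.append(feats)
        labels.extend([ci] * n_per_class)
    X = np.vstack(rows)
    y = np.asarray(labels, dtype=int)
    return TraitMatrix(X, y, tuple(FEATURE_NAMES))
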