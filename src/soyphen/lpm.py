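"""LPM — the leaf phenotype measurement chain.

Given a calibrated (cm), ground-aligned soybean plant cloud, this module
measures eleven morphological traits: plant height, plant bounding-box
volume, leaf count, and per leaf the bounding-box volume, length, width,
shell volume, projected area (Heron's formula summed over a greedy planar
triangulation of the xy projection), projected length and width, and tilt
information (RANSAC leaf-plane angle to the vertical).

Conventions
-----------
* Lengths in cm, areas in cm^2, volumes in cm^3, angles in degrees.
* The plant is assumed to grow along +z with the ground at z = 0; the
  horizontal principal direction is corrected to x before any axis-aligned
  box is measured, so results do not depend on the plant's orientation on
  the turntable.
* Leaf length is the Euclidean chord between the maximum-separation point
  pair (base/tip); width is the orthogonal extent inside the
  total-least-squares leaf plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist

from .cloud import PointCloud
from .geometry import PlaneModel, ransac_plane

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap
from .preprocess import gaussian_filter
from .segment import (
    ClusterSet,
    euclidean_cluster,
    laplacian_smooth,
    ols_plane_fit,
    ransac_cylinder,
    split_stem_leaves,
)

__all__ = [
    "TriangleMesh2D",
    "TiltInfo",
    "LeafTraits",
    "TraitRecord",
    "LPMConfig",
    "plant_height",
    "principal_axes_correction",
    "aabb_volume",
    "leaf_count",
    "leaf_length_width",
    "leaf_volume",
    "project_to_xy",
    "greedy_triangulate",
    "heron_area",
    "projection_extent",
    "leaf_tilt",
    "extract_all",
]


# ---------------------------------------------------------------------------
# data types

@dataclass
class TriangleMesh2D:
    """Planar triangulation with per-triangle Heron areas.

    ``sides`` holds (a, b, c) per triangle, ``semiperimeters`` p = (a+b+c)/2
    and ``areas`` the Heron areas; ``total_area`` is their sum.
    """

    vertices: np.ndarray            # (n, 2)
    triangles: np.ndarray           # (m, 3) vertex indices
    sides: np.ndarray               # (m, 3)
    semiperimeters: np.ndarray      # (m,)
    areas: np.ndarray               # (m,)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


@dataclass
class TiltInfo:
    """Leaf inclination: fitted plane, angle to vertical, downhill azimuth."""

    plane: PlaneModel
    tilt_angle: float       # degrees in [0, 90]
    tilt_azimuth: float     # degrees in [0, 360)
    fit_rmse: float         # cm


@dataclass
class LeafTraits:
    length_cm: float
    width_cm: float
    aabb_volume_cm3: float
    volume_cm3: float
    projection_area_cm2: float
    projection_length_cm: float
    projection_width_cm: float
    tilt: TiltInfo
    centroid_cm: Tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class TraitRecord:
    plant_height_cm: float
    plant_aabb_volume_cm3: float
    leaf_count: int
    leaves: List[LeafTraits]
    plant_id: str = "plant"


@dataclass
class LPMConfig:
    """Tunable parameters of the trait-extraction chain (all in cm).

    ``cluster_tol=None`` uses the scale-adaptive default of 3x the median
    nearest-neighbour distance of the leaf cloud.
    """

    cluster_tol: Optional[float] = None
    min_cluster_size: int = 60
    stem_dist_threshold: float = 0.15
    stem_radius_bounds: Tuple[float, float] = (0.05, 1.0)
    stem_margin: float = 0.3
    stem_max_axis_angle_deg: float = 30.0
    stem_ransac_iterations: int = 1200
    leaf_cell_size: float = 0.2
    leaf_gauss_sigma: Optional[float] = None   # None: no extra denoising
    tilt_dist_threshold: float = 0.5
    edge_cutoff: float = 4.0                   # x q95 NN distance
    smooth_leaves: bool = False
    smooth_k: int = 8
    smooth_lam: float = 0.5
    smooth_iterations: int = 2
    seed: int = 0

    def scaled(self, alpha: float) -> "LPMConfig":
        """Config with every length-dimension parameter multiplied by
        ``alpha`` — used to verify the calibration scaling laws."""
        return LPMConfig(
            cluster_tol=None if self.cluster_tol is None else self.cluster_tol * alpha,
            min_cluster_size=self.min_cluster_size,
            stem_dist_threshold=self.stem_dist_threshold * alpha,
            stem_radius_bounds=(
                self.stem_radius_bounds[0] * alpha,
                self.stem_radius_bounds[1] * alpha,
            ),
            stem_margin=self.stem_margin * alpha,
            stem_max_axis_angle_deg=self.stem_max_axis_angle_deg,
            stem_ransac_iterations=self.stem_ransac_iterations,
            leaf_cell_size=self.leaf_cell_size * alpha,
            leaf_gauss_sigma=None
            if self.leaf_gauss_sigma is None
            else self.leaf_gauss_sigma * alpha,
            tilt_dist_threshold=self.tilt_dist_threshold * alpha,
            edge_cutoff=self.edge_cutoff,
            smooth_leaves=self.smooth_leaves,
            smooth_k=self.smooth_k,
            smooth_lam=self.smooth_lam,
            smooth_iterations=self.smooth_iterations,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# plant-level traits

def plant_height(plant: PointCloud, ground_z: float = 0.0) -> float:
    """|max z - ground_z| for a ground-aligned plant cloud."""
    if len(plant) == 0:
        raise ValueError("empty cloud has no height")
    return float(abs(plant.points[:, 2].max() - ground_z))


def principal_axes_correction(
    pc: PointCloud, keep_z: bool = True
) -> Tuple[PointCloud, np.ndarray]:
    """Rotate the cloud onto its principal axes (descending variance).

    With ``keep_z`` (whole plants) only the horizontal principal direction
    is rotated to x, about the vertical axis; otherwise a full 3D PCA
    rotation is applied (single leaves).  Rotation is about the centroid;
    the applied matrix is returned for traceability.
    """
    pts = pc.points
    if len(pts) < 3:
        raise ValueError("need >= 3 points for principal-axis correction")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if keep_z:
        cov = np.cov(centered[:, :2].T)
        if not np.isfinite(cov).all():
            raise ValueError("degenerate covariance")
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        if v[0] < 0 or (v[0] == 0 and v[1] < 0):
            v = -v
        c, s = v[0], v[1]
        # rotate v onto +x about z
        R = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    else:
        cov = np.cov(centered.T)
        if not np.isfinite(cov).all():
            raise ValueError("degenerate covariance")
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        axes = evecs[:, order].T          # rows: principal directions
        for r in range(3):
            j = np.argmax(np.abs(axes[r]))
            if axes[r, j] < 0:
                axes[r] = -axes[r]
        if np.linalg.det(axes) < 0:
            axes[2] = -axes[2]
        R = axes
    rotated = centered @ R.T + centroid
    return pc.with_points(rotated), R


def aabb_volume(
    pc: PointCloud, keep_z: bool = True
) -> Tuple[float, np.ndarray]:
    """Axis-aligned bounding-box volume after principal-axes correction,
    plus the 8 corner points (in the corrected frame)."""
    if len(pc) == 0:
        raise ValueError("empty cloud has no bounding box")
    if len(pc) >= 3:
        corrected, _ = principal_axes_correction(pc, keep_z=keep_z)
    else:
        corrected = pc
    lo = corrected.points.min(axis=0)
    hi = corrected.points.max(axis=0)
    ext = hi - lo
    corners = np.array(
        [
            [x, y, z]
            for x in (lo[0], hi[0])
            for y in (lo[1], hi[1])
            for z in (lo[2], hi[2])
        ]
    )
    return float(np.prod(ext)), corners


def leaf_count(clusters: ClusterSet) -> int:
    """Number of non-noise clusters (one cluster per leaf)."""
    return clusters.n_clusters


# ---------------------------------------------------------------------------
# per-leaf traits

def _trimmed_extent(vals: np.ndarray, trim: int = 2, min_n: int = 20) -> float:
    """Noise-robust extent of a 1D coordinate set.

    The raw max-min extent of noisy samples is inflated by the extreme
    order statistics (~2-3 sigma of the sensor noise per side); dropping
    the ``trim`` outermost values per side leaves a nearly unbiased extent
    on dense clouds.  Small sets (< ``min_n``) use the exact extent.
    """
    v = np.sort(np.asarray(vals, dtype=np.float64))
    if len(v) >= min_n:
        return float(v[-1 - trim] - v[trim])
    return float(v[-1] - v[0])


def _max_distance_pair(pts: np.ndarray) -> Tuple[int, int, float]:
    """Indices and distance of the farthest point pair (exact)."""
    n = len(pts)
    if n == 2:
        return 0, 1, float(np.linalg.norm(pts[0] - pts[1]))
    cand = np.arange(n)
    if n > 500:
        try:
            hull = ConvexHull(pts)
            cand = hull.vertices
        except QhullError:
            pass  # flat/collinear leaf: fall through to full scan
    sub = pts[cand]
    d = pdist(sub)
    k = int(np.argmax(d))
    # invert condensed index
    m = len(sub)
    i = int(m - 2 - math.floor(math.sqrt(-8 * k + 4 * m * (m - 1) - 7) / 2 - 0.5))
    j = int(k + i + 1 - m * (m - 1) // 2 + (m - i) * ((m - i) - 1) // 2)
    return int(cand[i]), int(cand[j]), float(d[k])


def leaf_length_width(
    leaf: PointCloud,
) -> Tuple[float, float, np.ndarray, np.ndarray]:
    """Leaf length and width with the base/tip anchor points.

    Length is the Euclidean distance between the maximum-separation pair
    (base = the lower of the two).  Width is the maximum extent along the
    direction orthogonal to the base-tip axis within the
    total-least-squares leaf plane; for degenerate (collinear) leaves the
    width is 0.
    """
    pts = leaf.points
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points for a leaf, got {len(pts)}")
    i, j, length = _max_distance_pair(pts)
    if pts[i, 2] > pts[j, 2]:
        i, j = j, i
    base, tip = pts[i], pts[j]
    try:
        plane = ols_plane_fit(leaf)
        axis = tip - base
        axis_in_plane = axis - (axis @ plane.normal) * plane.normal
        na = np.linalg.norm(axis_in_plane)
        if na < 1e-12:
            return length, 0.0, base, tip
        u = axis_in_plane / na
        v = np.cross(plane.normal, u)
        width = _trimmed_extent((pts - base) @ v)
    except ValueError:
        width = 0.0
    width = min(width, length)
    return length, width, base, tip


def leaf_volume(
    leaf: PointCloud,
    cell_size: float,
    presmooth_sigma: Optional[float] = None,
) -> float:
    """Shell volume: occupied-voxel count x cell_size^3.

    ``presmooth_sigma`` optionally applies Gaussian denoising before
    voxelisation (useful on raw, un-denoised leaves); note that smoothing
    contracts the shell by roughly the sigma per open boundary, so leave
    it off (None) for clouds that are already clean.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if len(leaf) == 0:
        raise ValueError("empty leaf has no volume")
    if presmooth_sigma is not None and len(leaf) > 1:
        leaf = gaussian_filter(
            leaf, sigma=presmooth_sigma, radius=2.0 * presmooth_sigma
        )
    pts = leaf.points
    idx3 = np.floor((pts - pts.min(axis=0)) / cell_size).astype(np.int64)
    occupied = len(np.unique(idx3, axis=0))
    return float(occupied) * cell_size**3


def project_to_xy(leaf: PointCloud) -> np.ndarray:
    """Drop z: the (n, 2) footprint of an aligned leaf, order preserved."""
    return leaf.points[:, :2].copy()


def heron_area(a: float, b: float, c: float, rel_tol: float = 1e-9) -> float:
    """Triangle area from side lengths via the semiperimeter.

    Rounding-induced small negative radicands are clamped to zero; a
    violation of the triangle inequality beyond ``rel_tol`` (relative to
    the perimeter) is an error.
    """
    p = 0.5 * (a + b + c)
    slack = min(p - a, p - b, p - c)
    if slack < -rel_tol * max(p, 1e-300):
        raise ValueError(
            f"sides ({a}, {b}, {c}) violate the triangle inequality"
        )
    rad = p * max(p - a, 0.0) * max(p - b, 0.0) * max(p - c, 0.0)
    return float(np.sqrt(max(rad, 0.0)))


def _orient(p, q, r) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _cross_batch(p, q, i, j, A, B, ai, bi, eps: float) -> bool:
    """True if segment (p, q) crosses any of the segments (A[k], B[k]).

    "Crosses" means a proper interior intersection, or a positive-length
    collinear overlap; segments merely sharing an endpoint (indices
    ``i``/``j`` vs ``ai``/``bi``) do not cross unless collinear-overlapping.
    """
    d1 = (B[:, 0] - A[:, 0]) * (p[1] - A[:, 1]) - (B[:, 1] - A[:, 1]) * (p[0] - A[:, 0])
    d2 = (B[:, 0] - A[:, 0]) * (q[1] - A[:, 1]) - (B[:, 1] - A[:, 1]) * (q[0] - A[:, 0])
    d3 = (q[0] - p[0]) * (A[:, 1] - p[1]) - (q[1] - p[1]) * (A[:, 0] - p[0])
    d4 = (q[0] - p[0]) * (B[:, 1] - p[1]) - (q[1] - p[1]) * (B[:, 0] - p[0])
    proper = (((d1 > eps) & (d2 < -eps)) | ((d1 < -eps) & (d2 > eps))) & (
        ((d3 > eps) & (d4 < -eps)) | ((d3 < -eps) & (d4 > eps))
    )
    shares = (ai == i) | (ai == j) | (bi == i) | (bi == j)
    proper &= ~shares  # strict-sign test already excludes these, but be safe
    if proper.any():
        return True
    coll = (
        (np.abs(d1) <= eps)
        & (np.abs(d2) <= eps)
        & (np.abs(d3) <= eps)
        & (np.abs(d4) <= eps)
    )
    if coll.any():
        axis = 0 if abs(q[0] - p[0]) >= abs(q[1] - p[1]) else 1
        a_lo, a_hi = min(p[axis], q[axis]), max(p[axis], q[axis])
        o_lo = np.minimum(A[coll, axis], B[coll, axis])
        o_hi = np.maximum(A[coll, axis], B[coll, axis])
        if (np.minimum(a_hi, o_hi) - np.maximum(a_lo, o_lo) > eps).any():
            return True
    return False


@_njit(cache=True)
def _greedy_insert_nb(pts, ci, cj, cell, eps, cap):  # pragma: no cover - jit
    """Sequential greedy edge insertion over a uniform grid of accepted
    edges.  Returns (-1, ..) when a grid cell exceeds ``cap`` so the
    caller can retry with more headroom."""
    n_cand = len(ci)
    minx = pts[:, 0].min()
    miny = pts[:, 1].min()
    ncx = int((pts[:, 0].max() - minx) / cell) + 1
    ncy = int((pts[:, 1].max() - miny) / cell) + 1
    grid_count = np.zeros(ncx * ncy, dtype=np.int32)
    grid_edges = np.zeros((ncx * ncy, cap), dtype=np.int32)
    ea = np.empty(n_cand, dtype=np.int64)
    eb = np.empty(n_cand, dtype=np.int64)
    n_acc = 0
    for e in range(n_cand):
        i = ci[e]
        j = cj[e]
        p0 = pts[i, 0]
        p1 = pts[i, 1]
        q0 = pts[j, 0]
        q1 = pts[j, 1]
        cx0 = int((min(p0, q0) - minx) / cell)
        cx1 = int((max(p0, q0) - minx) / cell)
        cy0 = int((min(p1, q1) - miny) / cell)
        cy1 = int((max(p1, q1) - miny) / cell)
        ok = True
        for cx in range(cx0, cx1 + 1):
            for cy in range(cy0, cy1 + 1):
                c = cx * ncy + cy
                for t in range(grid_count[c]):
                    eid = grid_edges[c, t]
                    a = ea[eid]
                    b = eb[eid]
                    ax = pts[a, 0]
                    ay = pts[a, 1]
                    bx = pts[b, 0]
                    by = pts[b, 1]
                    d1 = (bx - ax) * (p1 - ay) - (by - ay) * (p0 - ax)
                    d2 = (bx - ax) * (q1 - ay) - (by - ay) * (q0 - ax)
                    d3 = (q0 - p0) * (ay - p1) - (q1 - p1) * (ax - p0)
                    d4 = (q0 - p0) * (by - p1) - (q1 - p1) * (bx - p0)
                    shared = a == i or a == j or b == i or b == j
                    if not shared:
                        s1 = (d1 > eps and d2 < -eps) or (d1 < -eps and d2 > eps)
                        s2 = (d3 > eps and d4 < -eps) or (d3 < -eps and d4 > eps)
                        if s1 and s2:
                            ok = False
                            break
                    if (
                        abs(d1) <= eps
                        and abs(d2) <= eps
                        and abs(d3) <= eps
                        and abs(d4) <= eps
                    ):
                        # collinear: positive-length overlap check
                        if abs(q0 - p0) >= abs(q1 - p1):
                            alo = min(p0, q0)
                            ahi = max(p0, q0)
                            blo = min(ax, bx)
                            bhi = max(ax, bx)
                        else:
                            alo = min(p1, q1)
                            ahi = max(p1, q1)
                            blo = min(ay, by)
                            bhi = max(ay, by)
                        if min(ahi, bhi) - max(alo, blo) > eps:
                            ok = False
                            break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            for cx in range(cx0, cx1 + 1):
                for cy in range(cy0, cy1 + 1):
                    c = cx * ncy + cy
                    if grid_count[c] >= cap:
                        return -1, ea, eb
                    grid_edges[c, grid_count[c]] = n_acc
                    grid_count[c] += 1
            ea[n_acc] = i
            eb[n_acc] = j
            n_acc += 1
    return n_acc, ea, eb


def _greedy_insert_py(pts, ci, cj, cell, eps):
    """Pure-numpy fallback for the greedy edge insertion (same contract as
    :func:`_greedy_insert_nb`, without the capacity limit)."""
    grid: dict = {}
    ea = np.empty(len(ci), dtype=np.int64)
    eb = np.empty(len(ci), dtype=np.int64)
    n_acc = 0

    def cells_of(p, q):
        cx0 = int(np.floor(min(p[0], q[0]) / cell))
        cy0 = int(np.floor(min(p[1], q[1]) / cell))
        cx1 = int(np.floor(max(p[0], q[0]) / cell))
        cy1 = int(np.floor(max(p[1], q[1]) / cell))
        return [
            (cx, cy) for cx in range(cx0, cx1 + 1) for cy in range(cy0, cy1 + 1)
        ]

    for i, j in zip(ci, cj):
        i = int(i)
        j = int(j)
        p, q = pts[i], pts[j]
        keys = cells_of(p, q)
        cand_ids: List[int] = []
        for key in keys:
            cand_ids.extend(grid.get(key, ()))
        if cand_ids:
            ids = np.unique(np.asarray(cand_ids, dtype=np.int64))
            ai = ea[ids]
            bi = eb[ids]
            if _cross_batch(p, q, i, j, pts[ai], pts[bi], ai, bi, eps):
                continue
        eid = n_acc
        ea[eid] = i
        eb[eid] = j
        n_acc += 1
        for key in keys:
            grid.setdefault(key, []).append(eid)
    return n_acc, ea, eb


def greedy_triangulate(
    points2d: np.ndarray, edge_cutoff: float = 4.0
) -> TriangleMesh2D:
    """Greedy planar triangulation of a 2D point set.

    Candidate edges shorter than ``edge_cutoff`` times the 95th-percentile
    nearest-neighbour distance are inserted in ascending length order,
    rejecting any edge that crosses an accepted one; triangles are then the
    empty 3-cliques of the resulting planar graph (3-cliques containing
    another vertex strictly inside are discarded, so triangles never
    overlap).  Per-triangle areas come from Heron's formula.

    The upper-quantile spacing makes the cutoff robust to how regular the
    sampling is: for Poisson-like scatters the longest needed boundary
    edges run to several times the *median* spacing, while for near-regular
    (voxel-thinned) sets median and q95 coincide — 4x q95 covers the
    footprint in both regimes without bridging separate structures.
    """
    pts = np.asarray(points2d, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points2d must be (n, 2)")
    n = len(pts)
    if n < 3:
        raise ValueError("need >= 3 points to triangulate")
    tree = cKDTree(pts)
    nn_d, _ = tree.query(pts, k=2)
    ref_nn = float(np.quantile(nn_d[:, 1], 0.95))
    if ref_nn <= 0:
        raise ValueError("duplicate points: cannot triangulate")
    cutoff = edge_cutoff * ref_nn
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no candidate edges within cutoff; increase edge_cutoff")
    vec = pts[pairs[:, 1]] - pts[pairs[:, 0]]
    lengths = np.hypot(vec[:, 0], vec[:, 1])
    order = np.lexsort((pairs[:, 1], pairs[:, 0], lengths))
    scale = max(float(np.abs(pts).max()), 1.0)
    eps = 1e-12 * scale * scale

    cell = max(cutoff / 2.0, 1e-12)
    ci = pairs[order, 0].astype(np.int64)
    cj = pairs[order, 1].astype(np.int64)
    if _HAVE_NUMBA:
        cap = 64
        while True:
            n_acc, ea, eb = _greedy_insert_nb(pts, ci, cj, cell, eps, cap)
            if n_acc >= 0:
                break
            cap *= 4  # a grid cell overflowed; retry with more headroom
    else:
        n_acc, ea, eb = _greedy_insert_py(pts, ci, cj, cell, eps)
    accepted = [(int(ea[k]), int(eb[k])) for k in range(n_acc)]
    adj: List[set] = [set() for _ in range(n)]
    for i, j in accepted:
        adj[i].add(j)
        adj[j].add(i)

    # enumerate empty 3-cliques
    tris = []
    for i, j in accepted:
        a, b = (i, j) if i < j else (j, i)
        for w in adj[a] & adj[b]:
            if w > b:
                tris.append((a, b, w))
    if not tris:
        raise ValueError("no triangles formed (points may be collinear)")
    tris = sorted(set(tris))
    kept = []
    for (a, b, c) in tris:
        pa, pb, pc_ = pts[a], pts[b], pts[c]
        area2 = abs(_orient(pa, pb, pc_))
        if area2 <= eps:
            continue
        # reject 3-cliques with another vertex strictly inside
        centroid = (pa + pb + pc_) / 3.0
        rmax = max(
            np.linalg.norm(pa - centroid),
            np.linalg.norm(pb - centroid),
            np.linalg.norm(pc_ - centroid),
        )
        inside = False
        for m in tree.query_ball_point(centroid, r=rmax + 1e-12):
            if m in (a, b, c):
                continue
            pm = pts[m]
            s1 = _orient(pa, pb, pm)
            s2 = _orient(pb, pc_, pm)
            s3 = _orient(pc_, pa, pm)
            ref = _orient(pa, pb, pc_)
            if ref < 0:
                s1, s2, s3 = -s1, -s2, -s3
            if s1 > eps and s2 > eps and s3 > eps:
                inside = True
                break
        if not inside:
            kept.append((a, b, c))
    if not kept:
        raise ValueError("triangulation degenerate: all triangles empty/flat")
    triangles = np.asarray(kept, dtype=np.int64)
    va = pts[triangles[:, 0]]
    vb = pts[triangles[:, 1]]
    vc = pts[triangles[:, 2]]
    sides = np.stack(
        [
            np.linalg.norm(vb - vc, axis=1),
            np.linalg.norm(va - vc, axis=1),
            np.linalg.norm(va - vb, axis=1),
        ],
        axis=1,
    )
    p = sides.sum(axis=1) / 2.0
    rad = (
        p
        * np.maximum(p - sides[:, 0], 0)
        * np.maximum(p - sides[:, 1], 0)
        * np.maximum(p - sides[:, 2], 0)
    )
    areas = np.sqrt(np.maximum(rad, 0.0))
    return TriangleMesh2D(
        vertices=pts,
        triangles=triangles,
        sides=sides,
        semiperimeters=p,
        areas=areas,
    )


def projection_extent(points2d: np.ndarray) -> Tuple[float, float]:
    """(length, width) of a 2D point set along its principal axes.

    Extents use the noise-robust trimmed extremes (see
    :func:`_trimmed_extent`); small sets fall back to exact max-min.
    """
    pts = np.asarray(points2d, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points2d must be a non-empty (n, 2) array")
    if len(pts) == 1:
        return 0.0, 0.0
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    proj = centered @ axes
    length = _trimmed_extent(proj[:, 0])
    width = _trimmed_extent(proj[:, 1])
    return length, width


def leaf_tilt(
    leaf: PointCloud, dist_threshold: float = 0.5, seed: int = 0
) -> TiltInfo:
    """RANSAC leaf plane; tilt angle between its (upward) normal and the
    vertical, in [0, 90] degrees, plus the downhill azimuth."""
    plane = ransac_plane(leaf, dist_threshold, max_iterations=300, seed=seed)
    normal = plane.normal
    if normal[2] < 0 or (
        normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))
    ):
        normal = -normal
        plane = PlaneModel(
            normal=normal,
            offset=-plane.offset,
            inlier_indices=plane.inlier_indices,
            rmse=plane.rmse,
            dist_threshold=plane.dist_threshold,
        )
    tilt = float(np.degrees(np.arccos(np.clip(abs(normal[2]), 0.0, 1.0))))
    horiz = np.hypot(normal[0], normal[1])
    if horiz < 1e-12:
        azimuth = 0.0
    else:
        azimuth = float(np.degrees(np.arctan2(normal[1], normal[0])) % 360.0)
    return TiltInfo(
        plane=plane, tilt_angle=tilt, tilt_azimuth=azimuth, fit_rmse=plane.rmse
    )


# ---------------------------------------------------------------------------
# full chain

class StageError(RuntimeError):
    """Pipeline-stage failure, carrying the failing stage's name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _leaf_traits(leaf: PointCloud, config: LPMConfig) -> LeafTraits:
    if config.smooth_leaves:
        leaf = laplacian_smooth(
            leaf,
            k=config.smooth_k,
            lam=config.smooth_lam,
            iterations=config.smooth_iterations,
        )
    length, width, _, _ = leaf_length_width(leaf)
    vol_box, _ = aabb_volume(leaf, keep_z=False)
    vol = leaf_volume(leaf, config.leaf_cell_size, config.leaf_gauss_sigma)
    proj = project_to_xy(leaf)
    mesh = greedy_triangulate(proj, edge_cutoff=config.edge_cutoff)
    p_len, p_wid = projection_extent(proj)
    tilt = leaf_tilt(leaf, config.tilt_dist_threshold, seed=config.seed)
    return LeafTraits(
        length_cm=length,
        width_cm=width,
        aabb_volume_cm3=vol_box,
        volume_cm3=vol,
        projection_area_cm2=mesh.total_area,
        projection_length_cm=p_len,
        projection_width_cm=p_wid,
        tilt=tilt,
        centroid_cm=tuple(leaf.points.mean(axis=0)),
    )


def extract_all(
    plant: PointCloud, config: Optional[LPMConfig] = None, plant_id: str = "plant"
) -> TraitRecord:
    """Run the full trait chain on a calibrated, aligned plant cloud.

    Stages: stem cylinder fit -> stem/leaf split -> per-leaf Euclidean
    clustering -> per-leaf traits -> plant traits.  Deterministic given
    ``config.seed``.  Stage failures are re-raised as :class:`StageError`
    naming the failing stage.
    """
    config = config or LPMConfig()
    if len(plant) == 0:
        raise StageError("input", ValueError("empty plant cloud"))
    try:
        height = plant_height(plant, 0.0)
        box_vol, _ = aabb_volume(plant, keep_z=True)
    except Exception as exc:
        raise StageError("plant_traits", exc) from exc
    try:
        cyl = ransac_cylinder(
            plant,
            dist_threshold=config.stem_dist_threshold,
            radius_bounds=config.stem_radius_bounds,
            max_iterations=config.stem_ransac_iterations,
            seed=config.seed,
            axis_hint=np.array([0.0, 0.0, 1.0]),
            max_axis_angle_deg=config.stem_max_axis_angle_deg,
        )
        _, leaves_pc = split_stem_leaves(plant, cyl, margin=config.stem_margin)
    except Exception as exc:
        raise StageError("stem_segmentation", exc) from exc
    try:
        tol = config.cluster_tol
        if tol is None:
            tree = cKDTree(leaves_pc.points)
            nn_d, _ = tree.query(leaves_pc.points, k=2)
            tol = 3.0 * float(np.median(nn_d[:, 1]))
        clusters = euclidean_cluster(leaves_pc, tol, config.min_cluster_size)
    except Exception as exc:
        raise StageError("leaf_clustering", exc) from exc
    leaves: List[LeafTraits] = []
    for li, members in enumerate(clusters.clusters):
        try:
            leaves.append(_leaf_traits(leaves_pc.select(members), config))
        except Exception as exc:
            raise StageError(f"leaf_traits[{li}]", exc) from exc
    return TraitRecord(
        plant_height_cm=height,
        plant_aabb_volume_cm3=box_vol,
        leaf_count=len(leaves),
        leaves=leaves,
        plant_id=plant_id,
    )
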