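"""Organ segmentation: stem extraction and per-leaf clustering.

The stalk is located with a RANSAC cylinder fit (two-point-with-normals
minimal sample); the remaining points are split into individual leaves by
Euclidean clustering, which assumes — as pot-grown soybean canopies at R4
permit — that a spatial gap exists between any two leaves.  Leaf surfaces
are refined with a total-least-squares plane fit and k-NN Laplacian
smoothing before meshing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .geometry import PlaneModel, _fit_plane_lsq
from .preprocess import knn_distance_stats

__all__ = [
    "ClusterSet",
    "CylinderModel",
    "euclidean_cluster",
    "estimate_normals",
    "ransac_cylinder",
    "split_stem_leaves",
    "ols_plane_fit",
    "laplacian_smooth",
]


@dataclass
class ClusterSet:
    """Partition of point indices into clusters (descending size) + noise."""

    clusters: List[np.ndarray]
    noise: np.ndarray
    tolerance: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class CylinderModel:
    """Cylinder: a point on the axis, unit axis direction, radius, inliers."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    inlier_indices: np.ndarray
    rmse: float
    dist_threshold: float = float("nan")

    def radial_residuals(self, points: np.ndarray) -> np.ndarray:
        """|distance to axis - radius| for each point."""
        return np.abs(self.axis_distances(points) - self.radius)

    def axis_distances(self, points: np.ndarray) -> np.ndarray:
        diff = points - self.axis_point
        along = diff @ self.axis_direction
        perp = diff - along[:, None] * self.axis_direction
        return np.linalg.norm(perp, axis=1)


def euclidean_cluster(
    pc: PointCloud, tolerance: float, min_cluster_size: int = 1
) -> ClusterSet:
    """Connected components of the graph linking points closer than
    ``tolerance``; components below ``min_cluster_size`` become noise.

    Clusters are returned sorted by descending size (ties by smallest
    member index), so the result is deterministic.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    n = len(pc)
    if n == 0:
        return ClusterSet([], np.empty(0, dtype=np.int64), tolerance)
    tree = cKDTree(pc.points)
    pairs = tree.query_pairs(r=tolerance, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs), dtype=np.int8)
        graph = sparse.coo_matrix(
            (data, (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    clusters = []
    noise_parts = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) >= min_cluster_size:
            clusters.append(members)
        else:
            noise_parts.append(members)
    clusters.sort(key=lambda m: (-len(m), m[0]))
    noise = (
        np.sort(np.concatenate(noise_parts))
        if noise_parts
        else np.empty(0, dtype=np.int64)
    )
    return ClusterSet(clusters, noise, tolerance)


def estimate_normals(points: np.ndarray, k: int = 10) -> np.ndarray:
    """Per-point unit normals from local PCA over the k-NN neighbourhood."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k + 1, len(points)))
    local = points[idx]                               # (n, k+1, 3)
    centered = local - local.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, evecs = np.linalg.eigh(cov)                    # ascending eigenvalues
    return np.ascontiguousarray(evecs[:, :, 0])


def _cylinder_from_two(p1, n1, p2, n2, axis=None):
    """Candidate cylinder from two oriented points.

    The axis is ``n1 x n2`` unless ``axis`` is given (e.g. a known growth
    direction), in which case the sample only determines center/radius.
    """
    if axis is None:
        w = np.cross(n1, n2)
        nw = np.linalg.norm(w)
        if nw < 1e-6:
            return None
        w = w / nw
    else:
        w = axis
    # work in the plane orthogonal to the axis
    u = n1 - (n1 @ w) * w
    v = n2 - (n2 @ w) * w
    q1 = p1 - (p1 @ w) * w
    q2 = p2 - (p2 @ w) * w
    # intersect lines q1 + t u and q2 + s v (2D system in the plane basis)
    b1 = u / max(np.linalg.norm(u), 1e-12)
    b2 = np.cross(w, b1)
    A = np.array(
        [[u @ b1, -(v @ b1)], [u @ b2, -(v @ b2)]]
    )
    rhs = np.array([(q2 - q1) @ b1, (q2 - q1) @ b2])
    det = np.linalg.det(A)
    if abs(det) < 1e-9:
        return None
    t, _ = np.linalg.solve(A, rhs)
    center = q1 + t * u
    radius = float(np.linalg.norm(q1 - center))
    return center, w, radius


def ransac_cylinder(
    pc: PointCloud,
    dist_threshold: float,
    radius_bounds: Tuple[float, float] = (1e-6, np.inf),
    max_iterations: int = 1000,
    seed: int = 0,
    axis_hint: Optional[np.ndarray] = None,
    max_axis_angle_deg: Optional[float] = None,
    normals_k: int = 10,
) -> CylinderModel:
    """RANSAC cylinder from two-point-with-normals minimal samples.

    Normals come from local PCA.  A candidate is kept only when its radius
    lies inside ``radius_bounds`` and, if ``axis_hint`` is given, its axis
    is within ``max_axis_angle_deg`` of the hint (used to keep the stem
    near vertical after ground alignment).  The best candidate is refined
    by nonlinear least squares on its inliers.  Deterministic given seed.
    """
    pts = pc.points
    n = len(pts)
    if n < 6:
        raise ValueError(f"need >= 6 points to fit a cylinder, got {n}")
    rmin, rmax = radius_bounds
    normals = estimate_normals(pts, k=normals_k)
    rng = np.random.default_rng(seed)
    cos_limit = (
        np.cos(np.deg2rad(max_axis_angle_deg))
        if (axis_hint is not None and max_axis_angle_deg is not None)
        else None
    )
    hint = (
        np.asarray(axis_hint, float) / np.linalg.norm(axis_hint)
        if axis_hint is not None
        else None
    )
    best = None
    best_count = -1
    for _ in range(max_iterations):
        i, j = rng.choice(n, size=2, replace=False)
        cands = [_cylinder_from_two(pts[i], normals[i], pts[j], normals[j])]
        if hint is not None:
            # noisy surface normals make the free axis unreliable; a
            # hint-constrained candidate from the same sample is cheap
            cands.append(
                _cylinder_from_two(pts[i], normals[i], pts[j], normals[j], axis=hint)
            )
        for cand in cands:
            if cand is None:
                continue
            center, w, radius = cand
            if not (rmin <= radius <= rmax):
                continue
            if cos_limit is not None and abs(w @ hint) < cos_limit:
                continue
            diff = pts - center
            along = diff @ w
            perp = diff - along[:, None] * w
            resid = np.abs(np.linalg.norm(perp, axis=1) - radius)
            count = int(np.count_nonzero(resid <= dist_threshold))
            if count > best_count:
                best_count = count
                best = (center, w, radius)
    if best is None:
        raise ValueError(
            "no cylinder candidate found within radius_bounds; "
            "check the bounds or the normals neighbourhood"
        )
    center, w, radius = best

    def pack(c, w, r):
        theta = np.arccos(np.clip(w[2], -1, 1))
        phi = np.arctan2(w[1], w[0])
        return np.r_[c, theta, phi, r]

    def unpack(x):
        c = x[:3]
        theta, phi, r = x[3], x[4], x[5]
        w = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        return c, w, r

    def count_inliers(c, wv, r):
        d = pts - c
        a = d @ wv
        p = d - a[:, None] * wv
        resid = np.abs(np.linalg.norm(p, axis=1) - r)
        return resid, int(np.count_nonzero(resid <= dist_threshold))

    cand_params = (center.copy(), w.copy(), float(radius))
    _, cand_count = count_inliers(*cand_params)

    # refine on a 2x-threshold band (so a slightly tilted initial axis can
    # recruit the far ends of the stem and straighten), re-select, repeat
    # until the band stabilises; reported inliers use the 1x threshold.
    # The radius stays clamped to radius_bounds during refinement.
    span = float(np.ptp(pts, axis=0).max()) + 1.0
    lo_b = np.r_[[-np.inf] * 5, max(rmin, 1e-9)]
    hi_b = np.r_[[np.inf] * 5, rmax if np.isfinite(rmax) else span]
    prev_mask = None
    for _ in range(10):
        diff = pts - center
        along = diff @ w
        perp = diff - along[:, None] * w
        resid = np.abs(np.linalg.norm(perp, axis=1) - radius)
        mask = resid <= 2.0 * dist_threshold
        if prev_mask is not None and np.array_equal(mask, prev_mask):
            break
        prev_mask = mask
        sub = pts[mask]
        if len(sub) < 6:
            break

        def fun(x):
            c, wv, r = unpack(x)
            d = sub - c
            a = d @ wv
            p = d - a[:, None] * wv
            return np.linalg.norm(p, axis=1) - r

        x0 = pack(center, w, radius)
        x0[5] = np.clip(x0[5], lo_b[5], hi_b[5])
        sol = least_squares(
            fun, x0, method="trf", bounds=(lo_b, hi_b), max_nfev=200
        )
        center, w, radius = unpack(sol.x)
        w = w / np.linalg.norm(w)
    # keep the refinement only if it did not lose consensus
    resid, refined_count = count_inliers(center, w, radius)
    if refined_count < cand_count:
        center, w, radius = cand_params
        resid, _ = count_inliers(center, w, radius)
    inliers = np.flatnonzero(resid <= dist_threshold)
    rmse = float(np.sqrt(np.mean(resid[inliers] ** 2))) if len(inliers) else float("nan")
    return CylinderModel(
        axis_point=center,
        axis_direction=w,
        radius=float(radius),
        inlier_indices=inliers,
        rmse=rmse,
        dist_threshold=dist_threshold,
    )


def split_stem_leaves(
    pc: PointCloud,
    cylinder: CylinderModel,
    margin: float = 0.0,
    junction_sor: Optional[Tuple[int, float]] = (8, 3.0),
    junction_band: float = 0.6,
) -> Tuple[PointCloud, PointCloud]:
    """Split a plant cloud into (stem, leaves) around a fitted cylinder.

    ``margin = 0`` returns exactly the cylinder's inlier set as the stem.
    ``margin > 0`` additionally claims every point within
    ``radius + margin`` of the axis segment spanned by the inliers.
    Leaf points within ``junction_band`` of the stem surface (the
    petiole/stem junction zone) are additionally cleaned with statistical
    outlier removal (``(k, n_sigma)`` in ``junction_sor``; None skips):
    stray points at the junctions have inflated neighbour distances, while
    leaf blades further out are left untouched.
    """
    pts = pc.points
    n = len(pts)
    stem_mask = np.zeros(n, dtype=bool)
    stem_mask[cylinder.inlier_indices] = True
    diff = pts - cylinder.axis_point
    along = diff @ cylinder.axis_direction
    perp = diff - along[:, None] * cylinder.axis_direction
    axial_dist = np.linalg.norm(perp, axis=1)
    if margin > 0:
        if len(cylinder.inlier_indices):
            t = along[cylinder.inlier_indices]
            lo, hi = t.min() - margin, t.max() + margin
        else:
            lo, hi = -np.inf, np.inf
        near = (axial_dist <= cylinder.radius + margin) & (along >= lo) & (along <= hi)
        stem_mask |= near
    stem = pc.select(stem_mask)
    leaf_mask = ~stem_mask
    if junction_sor is not None:
        band = leaf_mask & (
            axial_dist <= cylinder.radius + margin + junction_band
        )
        k, n_sigma = junction_sor
        if band.sum() > k + 1:
            band_idx = np.flatnonzero(band)
            stats = knn_distance_stats(pc.select(band_idx), k)
            drop = stats.d > stats.d_mean + n_sigma * stats.sigma
            leaf_mask = leaf_mask.copy()
            leaf_mask[band_idx[drop]] = False
    leaves = pc.select(leaf_mask)
    return stem, leaves


def ols_plane_fit(pc: PointCloud) -> PlaneModel:
    """Best-fit plane minimising orthogonal squared error (total least
    squares via the smallest singular vector of the centred coordinates)."""
    pts = pc.points if isinstance(pc, PointCloud) else np.asarray(pc, float)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points, got {len(pts)}")
    normal, offset = _fit_plane_lsq(pts)
    resid = pts @ normal + offset
    return PlaneModel(
        normal=normal,
        offset=offset,
        inlier_indices=np.arange(len(pts)),
        rmse=float(np.sqrt(np.mean(resid**2))),
        dist_threshold=float("inf"),
    )


def laplacian_smooth(
    pc: PointCloud, k: int = 8, lam: float = 0.5, iterations: int = 3
) -> PointCloud:
    """k-NN Laplacian smoothing: each iteration moves every point by
    ``lam * (mean of its k nearest neighbours - itself)``.

    The neighbour graph is built once from the input cloud and kept fixed
    across iterations, which makes the operator linear and deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 < lam <= 1):
        raise ValueError("lam must lie in (0, 1]")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    pts = pc.points.copy()
    n = len(pts)
    if iterations == 0 or n <= 1:
        return pc.copy()
    kk = min(k, n - 1)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=kk + 1)
    nbrs = idx[:, 1:]
    for _ in range(iterations):
        means = pts[nbrs].mean(axis=1)
        pts = pts + lam * (means - pts)
    return pc.with_points(pts)
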