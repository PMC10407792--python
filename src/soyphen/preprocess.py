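"""Downsampling and denoising of raw reconstruction clouds.

The raw SfM-MVS output is redundant and noisy: this module provides the
standard cleanup chain — voxel-grid downsampling (keep the original point
nearest each voxel's centroid), a local-plane low-pass filter, RGB
background removal, k-NN distance statistics with the classic
mean + n*sigma statistical outlier rule, and Gaussian neighbourhood
smoothing.  All operations keep the colors<->points pairing intact and are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "NeighborStats",
    "voxel_downsample",
    "lowpass_plane_filter",
    "color_background_filter",
    "knn_distance_stats",
    "statistical_outlier_removal",
    "gaussian_filter",
]


@dataclass(frozen=True)
class NeighborStats:
    """Per-point mean k-NN distances with their global mean and spread.

    ``d`` holds, for every point, the arithmetic mean of the Euclidean
    distances to its ``k`` nearest neighbours (self excluded).  ``d_mean``
    is the mean of ``d`` and ``sigma`` its population standard deviation
    (divide by n): a point is an outlier when its ``d`` exceeds
    ``d_mean + n_sigma * sigma``.
    """

    d: np.ndarray
    d_mean: float
    sigma: float
    k: int


def voxel_downsample(
    pc: PointCloud, voxel_size: float, origin=None
) -> PointCloud:
    """Keep one original point per occupied voxel: the point nearest the
    voxel's centroid (ties broken by lowest original index).

    By default the grid is anchored at the cloud's minimum corner, so the
    result does not depend on a global translation; pass ``origin`` to pin
    the grid explicitly (re-running on the output with the same origin is
    then exactly idempotent).  Output points are a subset of the input —
    no new coordinates are invented.
    """
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be > 0, got {voxel_size}")
    if len(pc) == 0:
        raise ValueError("cannot downsample an empty cloud")
    pts = pc.points
    origin = pts.min(axis=0) if origin is None else np.asarray(origin, float)
    idx3 = np.floor((pts - origin) / voxel_size).astype(np.int64)
    # collapse the 3D voxel index into a sortable key
    _, voxel_id = np.unique(idx3, axis=0, return_inverse=True)
    order = np.argsort(voxel_id, kind="stable")
    vid_sorted = voxel_id[order]
    starts = np.flatnonzero(np.r_[True, np.diff(vid_sorted) != 0])
    counts = np.diff(np.r_[starts, len(vid_sorted)])
    centroids = np.add.reduceat(pts[order], starts, axis=0) / counts[:, None]
    # distance of each (sorted) point to its voxel centroid
    diff = pts[order] - centroids[np.repeat(np.arange(len(starts)), counts)]
    dist2 = np.einsum("ij,ij->i", diff, diff)
    # within each voxel pick the minimal (distance, original index) pair:
    # sorting by (voxel, distance, index) puts the winner at each group
    # start, with exact-distance ties broken by the lowest original index
    pick = np.lexsort((order, dist2, vid_sorted))
    keep = np.sort(order[pick[starts]])
    return pc.select(keep)


def lowpass_plane_filter(
    pc: PointCloud, radius: float, max_error: float = 2.0
) -> PointCloud:
    """Remove points that deviate from their locally fitted plane.

    For every point, a total-least-squares plane is fitted to the points
    within ``radius`` (the point itself included).  The point is dropped
    when its orthogonal residual exceeds ``max_error`` times the RMS
    residual of that local fit.  Points with fewer than 3 neighbours are
    retained unchanged.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if max_error <= 0:
        raise ValueError("max_error must be > 0")
    pts = pc.points
    n = len(pts)
    if n == 0:
        return pc.copy()
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, r=radius)
    keep = np.ones(n, dtype=bool)
    for i, nb in enumerate(neighborhoods):
        if len(nb) - 1 < 3:  # fewer than 3 neighbours besides the point
            continue
        local = pts[nb]
        centroid = local.mean(axis=0)
        centered = local - centroid
        # smallest right singular vector = local plane normal
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[-1]
        resid = centered @ normal
        rms = float(np.sqrt(np.mean(resid**2)))
        own = abs(float((pts[i] - centroid) @ normal))
        if own > max_error * rms:
            keep[i] = False
    return pc.select(keep)


def color_background_filter(pc: PointCloud, background_ranges) -> PointCloud:
    """Drop every point whose RGB lies inside any background box.

    ``background_ranges`` is an iterable of ``((rmin, gmin, bmin),
    (rmax, gmax, bmax))`` inclusive boxes.  Raises if the cloud carries no
    colors (skip this stage for colorless clouds).
    """
    if not pc.has_colors:
        raise ValueError(
            "cloud has no colors; skip color_background_filter for colorless input"
        )
    cols = pc.colors.astype(np.int64)
    drop = np.zeros(len(pc), dtype=bool)
    for lo, hi in background_ranges:
        lo = np.asarray(lo)
        hi = np.asarray(hi)
        drop |= ((cols >= lo) & (cols <= hi)).all(axis=1)
    if drop.all():
        warnings.warn("color_background_filter removed every point", stacklevel=2)
    return pc.select(~drop)


def knn_distance_stats(pc: PointCloud, k: int) -> NeighborStats:
    """Mean distance of each point to its k nearest neighbours, with the
    global mean and population standard deviation of those means."""
    n = len(pc)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(pc.points)
    dist, _ = tree.query(pc.points, k=k + 1)  # first hit is the point itself
    d = dist[:, 1:].mean(axis=1)
    return NeighborStats(
        d=d, d_mean=float(d.mean()), sigma=float(d.std()), k=k
    )


def statistical_outlier_removal(
    pc: PointCloud, k: int, n_sigma: float
) -> PointCloud:
    """Remove point i iff its mean k-NN distance exceeds the global mean
    by more than ``n_sigma`` standard deviations."""
    if n_sigma <= 0:
        raise ValueError("n_sigma must be > 0")
    stats = knn_distance_stats(pc, k)
    keep = stats.d <= stats.d_mean + n_sigma * stats.sigma
    return pc.select(keep)


def gaussian_filter(pc: PointCloud, sigma: float, radius: float) -> PointCloud:
    """Replace each point by the Gaussian-weighted mean of its neighbours
    within ``radius`` (weight exp(-d^2 / 2 sigma^2), self included).

    Point count, colors and ordering are unchanged.
    """
    if sigma <= 0 or radius <= 0:
        raise ValueError("sigma and radius must be > 0")
    pts = pc.points
    if len(pts) == 0:
        return pc.copy()
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, r=radius)
    out = np.empty_like(pts)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for i, nb in enumerate(neighborhoods):
        local = pts[nb]
        d2 = np.einsum("ij,ij->i", local - pts[i], local - pts[i])
        w = np.exp(-d2 * inv2s2)
        out[i] = (w[:, None] * local).sum(axis=0) / w.sum()
    return pc.with_points(out)
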