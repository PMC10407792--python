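"""Reading and writing point clouds (PLY / PCD / XYZ) and trait tables.

PLY parsing is delegated to :mod:`trimesh` (which handles both ASCII and
binary little-endian vertex data); PLY writing emits ASCII with double
precision so that cm-scale coordinates survive a write->read round trip to
1e-6.  PCD support covers the v0.7 ASCII dialect that SfM toolchains emit;
XYZ is plain whitespace-delimited text with 3 (xyz) or 6 (xyzrgb) columns
and ``#`` comments.
"""

from __future__ import annotations

import os
from typing import List

import numpy as np
import pandas as pd
import trimesh

from .cloud import PointCloud

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "write_trait_table",
    "read_trait_table",
]

_EXT_FORMAT = {".ply": "ply", ".pcd": "pcd", ".xyz": "xyz", ".txt": "xyz"}


class PointCloudParseError(ValueError):
    """Raised when a point-cloud file is malformed."""


def _infer_format(path: str, format: str) -> str:
    if format != "auto":
        return format
    ext = os.path.splitext(path)[1].lower()
    try:
        return _EXT_FORMAT[ext]
    except KeyError:
        raise PointCloudParseError(
            f"cannot infer format from extension {ext!r} of {path!r}; "
            "pass format='ply'|'pcd'|'xyz'"
        )


def read_point_cloud(path: str, format: str = "auto") -> PointCloud:
    """Read a point cloud; the result always carries ``unit='raw'``.

    Colors are populated iff present in the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_point_cloud(pc: PointCloud, path: str, format: str = "auto") -> None:
    """Write ``pc`` so that :func:`read_point_cloud` round-trips it."""
    if len(pc) == 0:
        raise ValueError("refusing to write an empty point cloud")
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(pc, path)
    elif fmt == "pcd":
        _write_pcd(pc, path)
    elif fmt == "xyz":
        _write_xyz(pc, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# PLY

def _read_ply(path: str) -> PointCloud:
    try:
        obj = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:  # trimesh raises a zoo of types on bad headers
        raise PointCloudParseError(f"malformed PLY {path!r}: {exc}") from exc
    verts = np.asarray(obj.vertices, dtype=np.float64)
    colors = None
    # trimesh stores RGBA; a default all-grey array means "no color in file"
    raw_colors = getattr(obj, "colors", None)
    if raw_colors is not None and len(raw_colors) == len(verts):
        vc = np.asarray(raw_colors)
        if vc.size and not _is_trimesh_default_color(vc):
            colors = vc[:, :3].astype(np.uint8)
    if verts.size and not np.isfinite(verts).all():
        raise PointCloudParseError(f"non-finite vertex in {path!r}")
    return PointCloud(verts, colors, unit="raw")


def _is_trimesh_default_color(vc: np.ndarray) -> bool:
    # trimesh fabricates a uniform grey (102,102,102,255) when the file has
    # no color properties; treat that exact uniform fill as "absent".
    return bool((vc == np.array([102, 102, 102, 255], dtype=vc.dtype)).all())


def _write_ply(pc: PointCloud, path: str) -> None:
    n = len(pc)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if pc.has_colors:
            fh.write(
                "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            )
        fh.write("end_header\n")
        if pc.has_colors:
            for (x, y, z), (r, g, b) in zip(pc.points, pc.colors):
                fh.write(f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b}\n")
        else:
            for x, y, z in pc.points:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# PCD (v0.7 ASCII)

def _read_pcd(path: str) -> PointCloud:
    fields: List[str] = []
    n_expected = None
    data_started = False
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not data_started:
                key, _, rest = line.partition(" ")
                key = key.upper()
                if key == "FIELDS":
                    fields = rest.split()
                elif key == "POINTS":
                    n_expected = int(rest)
                elif key == "DATA":
                    if rest.strip().lower() != "ascii":
                        raise PointCloudParseError(
                            f"{path!r}: only DATA ascii PCD is supported, got {rest!r}"
                        )
                    data_started = True
                continue
            vals = line.split()
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise PointCloudParseError(
                    f"{path!r}: non-numeric value on line {lineno}: {line!r}"
                )
    if not data_started:
        raise PointCloudParseError(f"{path!r}: missing DATA section in PCD header")
    if not all(f in fields for f in ("x", "y", "z")):
        raise PointCloudParseError(f"{path!r}: PCD FIELDS lack x y z: {fields}")
    arr = np.asarray(rows, dtype=np.float64)
    if n_expected is not None and len(arr) != n_expected:
        raise PointCloudParseError(
            f"{path!r}: POINTS says {n_expected} but {len(arr)} records found"
        )
    ix = [fields.index(a) for a in ("x", "y", "z")]
    pts = arr[:, ix]
    colors = None
    if "rgb" in fields:
        packed = arr[:, fields.index("rgb")]
        # PCD packs RGB into a float whose bit pattern is 0x00RRGGBB
        as_int = packed.astype(np.float32).view(np.uint32)
        colors = np.stack(
            [(as_int >> 16) & 255, (as_int >> 8) & 255, as_int & 255], axis=1
        ).astype(np.uint8)
    elif all(c in fields for c in ("r", "g", "b")):
        ci = [fields.index(c) for c in ("r", "g", "b")]
        colors = arr[:, ci].astype(np.uint8)
    return PointCloud(pts, colors, unit="raw")


def _write_pcd(pc: PointCloud, path: str) -> None:
    n = len(pc)
    has_c = pc.has_colors
    fields = "x y z rgb" if has_c else "x y z"
    size = "4 4 4 4" if has_c else "4 4 4"
    types = "F F F F" if has_c else "F F F"
    count = "1 1 1 1" if has_c else "1 1 1"
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\n")
        fh.write(f"FIELDS {fields}\n")
        fh.write(f"SIZE {size}\nTYPE {types}\nCOUNT {count}\n")
        fh.write(f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {n}\nDATA ascii\n")
        if has_c:
            packed = (
                (pc.colors[:, 0].astype(np.uint32) << 16)
                | (pc.colors[:, 1].astype(np.uint32) << 8)
                | pc.colors[:, 2].astype(np.uint32)
            )
            rgb_f = packed.astype(np.uint32).view(np.float32)
            for (x, y, z), c in zip(pc.points, rgb_f):
                fh.write(f"{x:.17g} {y:.17g} {z:.17g} {c:.9g}\n")
        else:
            for x, y, z in pc.points:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# XYZ text

def _read_xyz(path: str) -> PointCloud:
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals = line.split()
            if len(vals) not in (3, 6):
                raise PointCloudParseError(
                    f"{path!r} line {lineno}: expected 3 or 6 columns, got {len(vals)}"
                )
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise PointCloudParseError(
                    f"{path!r} line {lineno}: inconsistent column count"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise PointCloudParseError(
                    f"{path!r} line {lineno}: non-numeric value in {line!r}"
                )
    if not rows:
        raise PointCloudParseError(f"{path!r}: no data records")
    arr = np.asarray(rows, dtype=np.float64)
    colors = arr[:, 3:6].astype(np.uint8) if arr.shape[1] == 6 else None
    return PointCloud(arr[:, :3], colors, unit="raw")


def _write_xyz(pc: PointCloud, path: str) -> None:
    with open(path, "w") as fh:
        if pc.has_colors:
            for (x, y, z), (r, g, b) in zip(pc.points, pc.colors):
                fh.write(f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b}\n")
        else:
            for x, y, z in pc.points:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# Trait tables

#: Column order of the per-leaf trait CSV.  Units are embedded in the names.
TRAIT_COLUMNS = [
    "plant_id",
    "row_type",            # "leaf" or "plant"
    "leaf_id",
    "plant_height_cm",
    "plant_aabb_volume_cm3",
    "leaf_count",
    "leaf_length_cm",
    "leaf_width_cm",
    "leaf_aabb_volume_cm3",
    "leaf_volume_cm3",
    "projection_area_cm2",
    "projection_length_cm",
    "projection_width_cm",
    "tilt_angle_deg",
    "tilt_azimuth_deg",
    "tilt_fit_rmse_cm",
]


def write_trait_table(records, path: str) -> None:
    """Write per-leaf rows plus one plant-level summary row per record.

    ``records`` is a list of :class:`soyphen.lpm.TraitRecord`.  Raises on an
    empty list.  Numeric values round-trip through the CSV to 1e-9.
    """
    if not records:
        raise ValueError("no trait records to write")
    rows = []
    for rec in records:
        for j, leaf in enumerate(rec.leaves):
            rows.append(
                {
                    "plant_id": rec.plant_id,
                    "row_type": "leaf",
                    "leaf_id": j,
                    "plant_height_cm": rec.plant_height_cm,
                    "plant_aabb_volume_cm3": rec.plant_aabb_volume_cm3,
                    "leaf_count": rec.leaf_count,
                    "leaf_length_cm": leaf.length_cm,
                    "leaf_width_cm": leaf.width_cm,
                    "leaf_aabb_volume_cm3": leaf.aabb_volume_cm3,
                    "leaf_volume_cm3": leaf.volume_cm3,
                    "projection_area_cm2": leaf.projection_area_cm2,
                    "projection_length_cm": leaf.projection_length_cm,
                    "projection_width_cm": leaf.projection_width_cm,
                    "tilt_angle_deg": leaf.tilt.tilt_angle,
                    "tilt_azimuth_deg": leaf.tilt.tilt_azimuth,
                    "tilt_fit_rmse_cm": leaf.tilt.fit_rmse,
                }
            )
        rows.append(
            {
                "plant_id": rec.plant_id,
                "row_type": "plant",
                "leaf_id": "",
                "plant_height_cm": rec.plant_height_cm,
                "plant_aabb_volume_cm3": rec.plant_aabb_volume_cm3,
                "leaf_count": rec.leaf_count,
            }
        )
    df = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# units: lengths cm, areas cm^2, volumes cm^3, angles degrees\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_trait_table(path: str) -> pd.DataFrame:
    """Re-parse a trait CSV written by :func:`write_trait_table`."""
    return pd.read_csv(path, comment="#")
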