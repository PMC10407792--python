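"""The point-cloud container shared by every pipeline stage.

A :class:`PointCloud` is a thin, immutable-by-convention wrapper around an
``(n, 3)`` float64 coordinate array with an optional parallel ``(n, 3)``
uint8 RGB array and a unit flag.  Reconstructed clouds start life in
arbitrary reconstruction units (``unit="raw"``); metric calibration against
a reference object of known size converts them to centimetres
(``unit="cm"``).  All filters preserve the points<->colors pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["PointCloud"]


@dataclass
class PointCloud:
    """3D points with optional per-point RGB color and a unit flag.

    Parameters
    ----------
    points : (n, 3) array_like of float
        Cartesian coordinates.  Must be finite.
    colors : (n, 3) array_like of int in [0, 255], optional
        Per-point RGB, parallel to ``points``.
    unit : {"raw", "cm"}
        "raw" for reconstruction units straight out of SfM-MVS, "cm" once
        the metric calibration has been applied.
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    unit: str = "raw"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        if self.colors is not None:
            cols = np.asarray(self.colors)
            if cols.shape != pts.shape:
                raise ValueError(
                    f"colors shape {cols.shape} does not match points shape {pts.shape}"
                )
            if cols.dtype != np.uint8:
                if cols.min(initial=0) < 0 or cols.max(initial=0) > 255:
                    raise ValueError("colors must lie in [0, 255]")
                cols = cols.astype(np.uint8)
            self.colors = cols
        if self.unit not in ("raw", "cm"):
            raise ValueError(f"unit must be 'raw' or 'cm', got {self.unit!r}")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, index) -> "PointCloud":
        """Return a sub-cloud at ``index`` (any numpy fancy index / mask)."""
        return PointCloud(
            self.points[index],
            None if self.colors is None else self.colors[index],
            self.unit,
        )

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same colors/unit, new coordinates (count must match colors)."""
        return PointCloud(points, self.colors, self.unit)

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            None if self.colors is None else self.colors.copy(),
            self.unit,
        )
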