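"""Voxel grid conventions shared by every module.

A volume is a plain ``numpy.ndarray`` indexed ``[i, j, k]`` plus a
:class:`Grid` carrying isotropic spacing and origin.  The physical
coordinate of voxel ``(i, j, k)`` is ``origin + (i + 0.5) * spacing``
(voxel-center convention); this one rule is used everywhere — by the
ellipsoid rasterizer, the contour rasterizer, centroid computation and
distance sampling — so simulated and rasterized inputs are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """An isotropic 3-D voxel grid with physical spacing in millimetres."""

    shape: tuple[int, int, int]
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres (1 cc = 1000 mm^3)."""
        return self.spacing_mm**3 / 1000.0

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical field of view along each axis, in mm."""
        return np.asarray(self.shape, dtype=float) * self.spacing_mm

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin_mm) + (idx + 0.5) * self.spacing_mm

    def containing_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Index of the voxel containing each physical point (floor rule)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = np.floor((pts - np.asarray(self.origin_mm)) / self.spacing_mm).astype(int)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm

    def check_same(self, other: "Grid") -> None:
        if self.shape != other.shape or not np.isclose(self.spacing_mm, other.spacing_mm):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.spacing_mm}mm vs "
                f"{other.shape}@{other.spacing_mm}mm"
            )
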