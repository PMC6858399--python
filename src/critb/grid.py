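"""Planar raster/vector geometry primitives.

All geometry is planar, in kilometres, on a uniform grid. The coordinate
convention is: origin at the lower-left corner, x increasing east, y
increasing north; cell indices are 0-based with row 0 at the *bottom*;
grid extents are half-open ``[origin, origin + n * cell_size)``. The cell
centre of cell ``(i, j)`` (row, column) therefore lies at
``(origin_x + (j + 0.5) * cell, origin_y + (i + 0.5) * cell)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint

__all__ = [
    "GridSpec",
    "Raster",
    "BinaryMask",
    "PointSet",
    "PatchSet",
    "connected_components",
    "buffer_mask",
    "convex_hull_area",
    "mask_area",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a uniform planar grid (km units)."""

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    origin_x_km: float = 0.0
    origin_y_km: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def total_area_km2(self) -> float:
        return self.n_rows * self.n_cols * self.cell_area_km2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of shape (n_rows, n_cols) with cell-centre coordinates."""
        j = np.arange(self.n_cols)
        i = np.arange(self.n_rows)
        x = self.origin_x_km + (j + 0.5) * self.cell_size_km
        y = self.origin_y_km + (i + 0.5) * self.cell_size_km
        return np.meshgrid(x, y)

    def point_to_cell(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices; raises if outside the grid."""
        j = np.floor((np.asarray(x) - self.origin_x_km) / self.cell_size_km).astype(int)
        i = np.floor((np.asarray(y) - self.origin_y_km) / self.cell_size_km).astype(int)
        if np.any(i < 0) or np.any(i >= self.n_rows) or np.any(j < 0) or np.any(j >= self.n_cols):
            raise ValueError("point(s) outside grid extent")
        return i, j

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.origin_x_km)
            & (x < self.origin_x_km + self.n_cols * self.cell_size_km)
            & (y >= self.origin_y_km)
            & (y < self.origin_y_km + self.n_rows * self.cell_size_km)
        )


@dataclass
class Raster:
    """A continuous or categorical grid layer.

    ``values`` has shape ``spec.shape`` with row 0 at the bottom. Categorical
    rasters declare their legal codes in ``categories``; any cell holding a
    value outside that set (other than ``nodata``) is invalid.
    """

    spec: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    kind: str = "continuous"  # "continuous" | "categorical"
    categories: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == "categorical" and self.categories is not None:
            valid = self.valid_mask()
            codes = np.unique(self.values[valid])
            unknown = [c for c in codes if int(c) not in self.categories]
            if unknown:
                raise ValueError(f"undeclared category codes in raster: {sorted(unknown)}")

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.spec, values, nodata=self.nodata, kind=self.kind, categories=self.categories)


@dataclass
class BinaryMask:
    spec: GridSpec
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != self.spec.shape:
            raise ValueError(
                f"mask shape {self.cells.shape} does not match grid {self.spec.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(self.cells.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        if other.spec != self.spec:
            raise ValueError("masks on different grids")
        return BinaryMask(self.spec, self.cells & other.cells)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        if other.spec != self.spec:
            raise ValueError("masks on different grids")
        return BinaryMask(self.spec, self.cells | other.cells)


@dataclass
class PointSet:
    """Points in planar km with optional per-point attribute columns."""

    xy: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("point coordinates must be finite")
        for name, col in self.attributes.items():
            col = np.asarray(col)
            if col.shape[0] != len(self.xy):
                raise ValueError(f"attribute {name!r} length mismatch")
            self.attributes[name] = col

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def subset(self, index: np.ndarray) -> "PointSet":
        return PointSet(self.xy[index], {k: v[index] for k, v in self.attributes.items()})


@dataclass
class PatchSet:
    """Dense labelling (1..K) of the connected components of a mask."""

    labels: np.ndarray
    n_patches: int
    connectivity: int

    def patch_mask(self, patch_id: int) -> np.ndarray:
        return self.labels == patch_id

    def sizes(self) -> np.ndarray:
        """Cell counts per patch, index 0 = patch 1."""
        if self.n_patches == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels.ravel(), minlength=self.n_patches + 1)[1:]


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def connected_components(mask: BinaryMask, connectivity: int = 8) -> PatchSet:
    """Partition true cells into maximal connected components.

    Labels are assigned in row-major order of the first-encountered cell of
    each component, so labelling is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask.cells, structure=_STRUCTURES[connectivity])
    return PatchSet(labels=labels, n_patches=int(n), connectivity=connectivity)


def buffer_mask(mask: BinaryMask, distance_km: float) -> BinaryMask:
    """Euclidean dilation of a mask by ``distance_km``.

    A cell is set in the output iff its centre lies within ``distance_km``
    (inclusive) of the centre of any input true cell. Exact centre-to-centre
    distances are used (via the Euclidean distance transform), so the result
    is independent of how the radius decomposes into cell offsets.
    """
    if distance_km < 0:
        raise ValueError("buffer distance must be non-negative")
    if not mask.cells.any() or distance_km == 0:
        return BinaryMask(mask.spec, mask.cells.copy())
    cell = mask.spec.cell_size_km
    dist = ndimage.distance_transform_edt(~mask.cells, sampling=cell)
    # guard against float fuzz at exactly-representable radii (e.g. 2.0 km)
    return BinaryMask(mask.spec, dist <= distance_km * (1 + 1e-12))


def convex_hull_area(points: PointSet) -> float:
    """Area (km²) of the minimum convex polygon around a point set.

    Degenerate sets (single point, duplicates, collinear) have area 0.
    """
    if len(points) == 0:
        raise ValueError("convex hull of an empty point set is undefined")
    hull = MultiPoint(points.xy).convex_hull
    return float(hull.area)


def mask_area(mask: BinaryMask) -> float:
    """Total area (km²) of the true cells."""
    return mask.n_true * mask.spec.cell_area_km2
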