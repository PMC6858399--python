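"""EOO, AOO and elevation range from a filtered binary range map.

EOO is the area of the minimum convex polygon around occupied-cell
centres, floored at AOO (IUCN consistency rule: EOO can never be smaller
than AOO). AOO overlays the IUCN-standard 2×2 km grid, aligned to the
raster origin, and counts occupied 2-km cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PointSet, Raster, convex_hull_area
from .sdm import RangeMap

__all__ = ["RangeMetrics", "eoo", "aoo", "elevation_range", "compute_range_metrics"]


@dataclass
class RangeMetrics:
    eoo_km2: float
    aoo_km2: float
    elev_min_m: float | None = None
    elev_max_m: float | None = None


def _occupied_centers(range_map: RangeMap) -> np.ndarray:
    spec = range_map.mask.spec
    i, j = np.nonzero(range_map.mask.cells)
    if len(i) == 0:
        raise ValueError("range mask is empty")
    x = spec.origin_x_km + (j + 0.5) * spec.cell_size_km
    y = spec.origin_y_km + (i + 0.5) * spec.cell_size_km
    return np.column_stack([x, y])


def aoo(range_map: RangeMap, aoo_cell_km: float = 2.0) -> float:
    """Area of occupancy (km²) on an ``aoo_cell_km`` grid aligned to the raster origin."""
    spec = range_map.mask.spec
    centers = _occupied_centers(range_map)
    bi = np.floor((centers[:, 1] - spec.origin_y_km) / aoo_cell_km).astype(int)
    bj = np.floor((centers[:, 0] - spec.origin_x_km) / aoo_cell_km).astype(int)
    n_blocks = len(np.unique(bi.astype(np.int64) << 32 | bj.astype(np.int64)))
    return n_blocks * aoo_cell_km**2


def eoo(range_map: RangeMap, aoo_cell_km: float = 2.0) -> float:
    """Extent of occurrence (km²): convex-hull area of occupied centres, floored at AOO."""
    hull_area = convex_hull_area(PointSet(_occupied_centers(range_map)))
    return max(hull_area, aoo(range_map, aoo_cell_km))


def elevation_range(range_map: RangeMap, dem: Raster) -> tuple[float, float]:
    """(min, max) DEM value (m) over occupied non-nodata cells."""
    if dem.spec != range_map.mask.spec:
        raise ValueError("DEM and range on different grids")
    if not range_map.mask.cells.any():
        raise ValueError("range mask is empty")
    vals = dem.values[range_map.mask.cells & dem.valid_mask()]
    if len(vals) == 0:
        raise ValueError("all occupied cells are nodata in the DEM")
    return float(vals.min()), float(vals.max())


def compute_range_metrics(
    range_map: RangeMap, dem: Raster | None = None, aoo_cell_km: float = 2.0
) -> RangeMetrics:
    a = aoo(range_map, aoo_cell_km)
    e = eoo(range_map, aoo_cell_km)
    lo = hi = None
    if dem is not None:
        lo, hi = elevation_range(range_map, dem)
    return RangeMetrics(eoo_km2=e, aoo_km2=a, elev_min_m=lo, elev_max_m=hi)
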