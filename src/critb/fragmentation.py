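"""Low-quality-habitat construction and the RA_LQH fragmentation statistic.

Low-quality habitat (LQH) is the anthropogenically disturbed part of the
landscape — crop, urban, water and bare land-use classes — dilated by a
threat-influence buffer (default 2 km) and intersected with the species'
binary range. The fragmentation statistic weights area by the SDM
suitability used as a relative-density proxy:

    RA_LQH = 100 * Σ_LQH-patches (area × mean prob)
                 / Σ_range-patches (area × mean prob)

which is identically the ratio of cellwise probability-weighted areas
(the patch decomposition is retained only for reporting). A species is
flagged severely fragmented when RA_LQH strictly exceeds the 50%
threshold: the majority of its predicted population would then sit in
disturbed, low-viability habitat.

Buffering is applied to all anthropogenic cells *before* intersecting
with the range, so disturbance just outside the range still contaminates
edge cells — the buffer represents a threat-influence zone extending
beyond the disturbed area itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask, Raster, buffer_mask, connected_components
from .landscape import ANTHROPOGENIC_CLASSES, LANDUSE_CODES
from .sdm import RangeMap

__all__ = [
    "LqhConfig",
    "LqhPolygonSummary",
    "RangePolygonSummary",
    "FragmentationResult",
    "lqh_mask",
    "ra_lqh",
    "classify_fragmentation",
]


@dataclass(frozen=True)
class LqhConfig:
    anthropogenic_codes: frozenset[str] = ANTHROPOGENIC_CLASSES
    buffer_km: float = 2.0
    severe_threshold_percent: float = 50.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.buffer_km < 0:
            raise ValueError("buffer_km must be non-negative")
        if not 0 < self.severe_threshold_percent < 100:
            raise ValueError("severe_threshold_percent must be in (0, 100)")


@dataclass
class LqhPolygonSummary:
    patch_id: int
    area_km2: float
    mean_prob: float


@dataclass
class RangePolygonSummary:
    patch_id: int
    area_km2: float
    mean_prob: float


@dataclass
class FragmentationResult:
    ra_lqh_percent: float
    severely_fragmented: bool
    lqh_polygons: list[LqhPolygonSummary]
    range_polygons: list[RangePolygonSummary]


def lqh_mask(
    landuse: Raster,
    range_map: RangeMap,
    config: LqhConfig = LqhConfig(),
    code_table: dict[int, str] | None = None,
) -> BinaryMask:
    """Build the low-quality-habitat mask within a species range.

    Anthropogenic land-use cells are dilated by ``config.buffer_km``
    (centre-to-centre Euclidean distance) and the result intersected with
    the binary range mask.
    """
    if code_table is None:
        code_table = LANDUSE_CODES
    if landuse.spec != range_map.mask.spec:
        raise ValueError("land-use raster and range on different grids")
    valid = landuse.valid_mask()
    present = {int(c) for c in np.unique(landuse.values[valid])}
    unknown = sorted(present - set(code_table))
    if unknown:
        raise ValueError(f"unknown land-use codes: {unknown}")
    missing = config.anthropogenic_codes - set(code_table.values())
    if missing:
        raise ValueError(f"anthropogenic classes not in code table: {sorted(missing)}")
    anthro_codes = [c for c, name in code_table.items() if name in config.anthropogenic_codes]
    anthro = BinaryMask(landuse.spec, np.isin(landuse.values, anthro_codes) & valid)
    dilated = buffer_mask(anthro, config.buffer_km)
    return dilated & range_map.mask


def _patch_summaries(mask: BinaryMask, prob: np.ndarray, connectivity: int, cls):
    patches = connected_components(mask, connectivity)
    cell_area = mask.spec.cell_area_km2
    out = []
    for pid in range(1, patches.n_patches + 1):
        cells = patches.labels == pid
        out.append(
            cls(
                patch_id=pid,
                area_km2=float(cells.sum()) * cell_area,
                mean_prob=float(prob[cells].mean()),
            )
        )
    return out


def ra_lqh(
    suitability: Raster,
    range_map: RangeMap,
    lqh: BinaryMask,
    config: LqhConfig = LqhConfig(),
) -> FragmentationResult:
    """Suitability-weighted share (%) of the range lying in low-quality habitat.

    Numerator and denominator are computed cellwise (area × probability
    summed over LQH cells and over all range cells respectively); the
    per-patch tables report the same quantities aggregated by connected
    component and satisfy Σ area×mean_prob = cellwise sum exactly.
    """
    range_cells = range_map.mask.cells
    if not range_cells.any():
        raise ValueError("range mask is empty")
    if suitability.spec != range_map.mask.spec or lqh.spec != range_map.mask.spec:
        raise ValueError("inputs on different grids")
    lqh_cells = lqh.cells & range_cells  # enforce LQH ⊆ range
    prob = suitability.values
    cell_area = range_map.mask.spec.cell_area_km2
    denom = float(prob[range_cells].sum()) * cell_area
    if denom <= 0:
        raise ValueError("suitability sums to zero over the range")
    numer = float(prob[lqh_cells].sum()) * cell_area
    pct = 100.0 * numer / denom
    return FragmentationResult(
        ra_lqh_percent=pct,
        severely_fragmented=classify_fragmentation(pct, config),
        lqh_polygons=_patch_summaries(
            BinaryMask(lqh.spec, lqh_cells), prob, config.connectivity, LqhPolygonSummary
        ),
        range_polygons=_patch_summaries(
            range_map.mask, prob, config.connectivity, RangePolygonSummary
        ),
    )


def classify_fragmentation(ra_lqh_percent: float, config: LqhConfig = LqhConfig()) -> bool:
    """Severe fragmentation iff RA_LQH strictly exceeds the threshold (default 50%)."""
    if not 0 <= ra_lqh_percent <= 100:
        raise ValueError("ra_lqh_percent must be in [0, 100]")
    return ra_lqh_percent > config.severe_threshold_percent
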