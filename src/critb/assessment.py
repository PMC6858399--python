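"""Per-species assessment assembly and the restricted-distribution screens.

``run_assessment`` executes the whole evidence chain — PCA reduction,
SDM fit, thresholding, the two precautionary range filters, EOO / AOO /
elevation range, the LQH fragmentation statistic, threat-based locations
counting, and the restricted-distribution screens (EOO < 20,000 km² and
AOO < 2,000 km², both strict) — deterministically under the configured
seed, and records provenance digests of every input.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fragmentation import FragmentationResult, LqhConfig, lqh_mask, ra_lqh
from .grid import PointSet, Raster
from .locations import LocationsConfig, LocationsResult, count_locations
from .range_metrics import RangeMetrics, compute_range_metrics
from .sdm import (
    RangeMap,
    SdmEvaluation,
    apply_expert_mask,
    binarize_range,
    evaluate_sdm,
    filter_patches,
    fit_sdm,
    pca_reduce,
)

__all__ = ["AssessmentConfig", "AssessmentRecord", "restricted_screen", "run_assessment"]

logger = logging.getLogger("critb")


@dataclass
class AssessmentConfig:
    lqh: LqhConfig = field(default_factory=LqhConfig)
    locations: LocationsConfig = field(default_factory=LocationsConfig)
    eoo_restricted_km2: float = 20000.0
    aoo_restricted_km2: float = 2000.0
    aoo_cell_km: float = 2.0
    n_replicates: int = 10
    n_background: int | None = None
    regularization: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eoo_restricted_km2 <= 0 or self.aoo_restricted_km2 <= 0:
            raise ValueError("restriction thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssessmentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        lqh_raw = raw.pop("lqh", {})
        if "anthropogenic_codes" in lqh_raw:
            lqh_raw["anthropogenic_codes"] = frozenset(lqh_raw["anthropogenic_codes"])
        loc_raw = raw.pop("locations", {})
        return cls(lqh=LqhConfig(**lqh_raw), locations=LocationsConfig(**loc_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "lqh": {
                "anthropogenic_codes": sorted(self.lqh.anthropogenic_codes),
                "buffer_km": self.lqh.buffer_km,
                "severe_threshold_percent": self.lqh.severe_threshold_percent,
                "connectivity": self.lqh.connectivity,
            },
            "locations": {
                "min_population": self.locations.min_population,
                "locality_radius_km": self.locations.locality_radius_km,
            },
            "eoo_restricted_km2": self.eoo_restricted_km2,
            "aoo_restricted_km2": self.aoo_restricted_km2,
            "aoo_cell_km": self.aoo_cell_km,
            "n_replicates": self.n_replicates,
            "n_background": self.n_background,
            "regularization": self.regularization,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class AssessmentRecord:
    species_id: str
    range_metrics: RangeMetrics
    fragmentation: FragmentationResult
    locations: LocationsResult
    sdm_eval_train: SdmEvaluation
    screens: dict[str, bool]
    provenance: dict


def restricted_screen(metrics: RangeMetrics, config: AssessmentConfig) -> dict[str, bool]:
    """Restricted-distribution flags: strict 'smaller than' on both thresholds."""
    return {
        "eoo_restricted": bool(metrics.eoo_km2 < config.eoo_restricted_km2),
        "aoo_restricted": bool(metrics.aoo_km2 < config.aoo_restricted_km2),
    }


def _digest(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def run_assessment(
    occurrences: PointSet,
    env_layers: list[Raster],
    landuse: Raster,
    dem: Raster,
    villages: PointSet,
    categorical_layers: dict[str, Raster] | None = None,
    expert_polygons: list | None = None,
    config: AssessmentConfig | None = None,
    species_id: str = "species_1",
) -> AssessmentRecord:
    """Run the full criterion-B evidence chain for one species.

    Stages (in order): pca_reduce → fit_sdm → binarize_range →
    filter_patches → apply_expert_mask → range metrics → lqh_mask →
    ra_lqh → count_locations → restricted_screen. Deterministic given
    ``config.seed``; stage failures are re-raised with the stage name.
    """
    if config is None:
        config = AssessmentConfig()
    stages: list[tuple[str, float]] = []

    def _stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"assessment stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        stages.append((name, dt))
        logger.info("stage=%s elapsed=%.3fs", name, dt)
        return out

    fs, pc_rasters = _stage("pca_reduce", pca_reduce, env_layers)
    model, suitability = _stage(
        "fit_sdm",
        fit_sdm,
        occurrences,
        pc_rasters,
        categorical_layers,
        config.n_background,
        config.n_replicates,
        config.regularization,
        config.seed,
    )
    # calibration background for thresholding/evaluation: a deterministic
    # uniform point sample over valid cells, disjoint from the fit stream
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1_000_003]))
    spec = suitability.spec
    valid = suitability.valid_mask()
    i, j = np.nonzero(valid)
    pick = rng.choice(len(i), size=min(10 * len(occurrences), len(i)), replace=False)
    bg_points = PointSet(
        np.column_stack(
            [
                spec.origin_x_km + (j[pick] + 0.5) * spec.cell_size_km,
                spec.origin_y_km + (i[pick] + 0.5) * spec.cell_size_km,
            ]
        )
    )
    range_map = _stage("binarize_range", binarize_range, suitability, occurrences, bg_points)
    sdm_eval = _stage(
        "evaluate_sdm", evaluate_sdm, suitability, occurrences, bg_points, range_map.threshold_used
    )
    range_map = _stage("filter_patches", filter_patches, range_map, occurrences, config.lqh.connectivity)
    if expert_polygons is not None:
        range_map = _stage("apply_expert_mask", apply_expert_mask, range_map, expert_polygons)
    metrics = _stage("range_metrics", compute_range_metrics, range_map, dem, config.aoo_cell_km)
    lqh = _stage("lqh_mask", lqh_mask, landuse, range_map, config.lqh)
    frag = _stage("ra_lqh", ra_lqh, suitability, range_map, lqh, config.lqh)
    locs = _stage("count_locations", count_locations, villages, range_map, config.locations)
    screens = restricted_screen(metrics, config)

    provenance = {
        "seed": config.seed,
        "threshold_used": range_map.threshold_used,
        "filters_applied": range_map.filters_applied,
        "n_occurrences": len(occurrences),
        "input_digests": {
            "occurrences": _digest(occurrences.xy),
            "env_layers": _digest(*[l.values for l in env_layers]),
            "landuse": _digest(landuse.values),
            "dem": _digest(dem.values),
            "villages": _digest(villages.xy, np.asarray(villages.attributes["population"])),
        },
        "stage_timings_s": {n: round(t, 4) for n, t in stages},
    }
    return AssessmentRecord(
        species_id=species_id,
        range_metrics=metrics,
        fragmentation=frag,
        locations=locs,
        sdm_eval_train=sdm_eval,
        screens=screens,
        provenance=provenance,
    )
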