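"""Synthetic study-system generator with known truth.

Emulates the inputs a criterion-B assessment consumes in the field —
stacks of spatially autocorrelated bioclimatic layers, categorical soil /
vegetation / ecoregion maps, an anthropogenic land-use mosaic, a DEM, a
village point pattern with settlement sizes — together with a known
species–environment relationship, so that every downstream statistic can
be checked against ground truth.

Reproducibility: a single master seed is split into per-stage child
streams via ``numpy.random.SeedSequence([master_seed, STAGE_INDEX])``
(stage indices are the module-level ``STAGE_*`` constants), so any
component can be regenerated on its own without consuming another
stage's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, GridSpec, PointSet, Raster

__all__ = [
    "LANDUSE_CODES",
    "ANTHROPOGENIC_CLASSES",
    "TruthParams",
    "LandscapeBundle",
    "generate_env_layers",
    "generate_categorical_layer",
    "generate_landuse",
    "generate_dem",
    "generate_villages",
    "true_suitability",
    "sample_occurrences",
    "generate_bundle",
]

# Land-use legend shared by the generator and the fragmentation stage.
LANDUSE_CODES: dict[int, str] = {
    1: "forest",
    2: "shrubland",
    3: "grassland",
    11: "crop",
    12: "urban",
    13: "water",
    14: "bare",
}
ANTHROPOGENIC_CLASSES = frozenset({"crop", "urban", "water", "bare"})
# relative mix of disturbance classes within the anthropogenic mosaic
_ANTHRO_MIX = {"crop": 0.55, "urban": 0.20, "water": 0.10, "bare": 0.15}

# seed-splitting stage indices (documented scheme; keep stable)
STAGE_ENV = 0
STAGE_SOIL = 1
STAGE_VEGETATION = 2
STAGE_ECOREGION = 3
STAGE_LANDUSE = 4
STAGE_DEM = 5
STAGE_VILLAGES = 6
STAGE_OCCURRENCES = 7


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def _smooth_field(spec: GridSpec, scale_km: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise, re-standardised to mean 0 / sd 1."""
    z = rng.standard_normal(spec.shape)
    if scale_km > 0:
        z = ndimage.gaussian_filter(z, sigma=scale_km / spec.cell_size_km, mode="reflect")
    z -= z.mean()
    sd = z.std()
    if sd > 0:
        z /= sd
    return z


@dataclass(frozen=True)
class TruthParams:
    """The generating species–environment relationship.

    Suitability is ``logistic(intercept + Σ βk·envk + categorical effects)``;
    the true range is the set of cells at or above ``occupancy_threshold``.
    """

    intercept: float = -5.0
    env_coefficients: tuple[float, ...] = (2.0, -2.0, 2.0, -2.0)
    categorical_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    occupancy_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.occupancy_threshold < 1:
            raise ValueError("occupancy_threshold must be in (0, 1)")


@dataclass
class LandscapeBundle:
    """A complete synthetic study system with its generating truth."""

    spec: GridSpec
    env_layers: list[Raster]
    soil: Raster
    vegetation: Raster
    ecoregion: Raster
    landuse: Raster
    dem: Raster
    villages: PointSet
    truth: TruthParams
    true_suitability: Raster
    true_range: BinaryMask
    seed: int
    occurrences: PointSet | None = None


def generate_env_layers(
    spec: GridSpec,
    n_layers: int = 19,
    autocorr_scale_km: float = 10.0,
    seed: int = 0,
    n_latent: int = 2,
    independent_noise: float = 0.3,
) -> list[Raster]:
    """Spatially autocorrelated continuous layers (zero mean, unit variance).

    Bioclimatic variable stacks are strongly collinear — families of
    temperature and precipitation summaries derived from the same few
    climatic gradients — which is why two principal components capture
    most of their variance. The generator reproduces that structure:
    ``n_latent`` shared smooth fields (default 2: the two dominant climatic gradients, e.g. temperature and moisture) are mixed with random unit weights
    into each layer, plus a smaller independent smooth component
    (``independent_noise`` relative weight). ``n_latent >= n_layers`` (or
    ``independent_noise`` large) degrades gracefully toward independent
    fields. Autocorrelation is controlled by the Gaussian smoothing
    bandwidth ``autocorr_scale_km``; 0 gives white noise.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = _rng(seed, STAGE_ENV)
    n_latent = min(n_latent, n_layers)
    latents = [_smooth_field(spec, autocorr_scale_km, rng) for _ in range(n_latent)]
    layers = []
    for _ in range(n_layers):
        w = rng.standard_normal(n_latent)
        w /= np.linalg.norm(w)
        z = sum(wk * lk for wk, lk in zip(w, latents))
        if independent_noise > 0:
            z = z + independent_noise * _smooth_field(spec, autocorr_scale_km, rng)
        z -= z.mean()
        z /= max(z.std(), 1e-12)
        layers.append(Raster(spec, z))
    return layers


def generate_categorical_layer(
    spec: GridSpec,
    n_categories: int,
    clustering_scale_km: float,
    seed: int,
    stage: int,
    names: list[str] | None = None,
) -> Raster:
    """Categorical raster formed by quantile-binning a smooth latent field."""
    rng = _rng(seed, stage)
    z = _smooth_field(spec, clustering_scale_km, rng)
    edges = np.quantile(z, np.linspace(0, 1, n_categories + 1)[1:-1])
    codes = np.digitize(z, edges) + 1  # codes 1..n_categories
    categories = {
        k + 1: (names[k] if names else f"class_{k + 1}") for k in range(n_categories)
    }
    return Raster(spec, codes.astype(float), kind="categorical", categories=categories)


def generate_landuse(
    spec: GridSpec,
    anthropogenic_fraction: float = 0.3,
    clustering_scale_km: float = 5.0,
    seed: int = 0,
) -> Raster:
    """Land-use mosaic with a controlled disturbed fraction.

    A smooth latent field is thresholded at its empirical
    ``1 - anthropogenic_fraction`` quantile, so the realised disturbed
    fraction matches the request up to ties. Disturbed cells are divided
    among crop / urban / water / bare; the rest among the natural classes.
    """
    if not 0 <= anthropogenic_fraction <= 1:
        raise ValueError("anthropogenic_fraction must be in [0, 1]")
    rng = _rng(seed, STAGE_LANDUSE)
    z = _smooth_field(spec, clustering_scale_km, rng)
    if anthropogenic_fraction <= 0:
        anthro = np.zeros(spec.shape, dtype=bool)
    elif anthropogenic_fraction >= 1:
        anthro = np.ones(spec.shape, dtype=bool)
    else:
        anthro = z >= np.quantile(z, 1 - anthropogenic_fraction)

    name_to_code = {v: k for k, v in LANDUSE_CODES.items()}
    codes = np.empty(spec.shape, dtype=float)
    natural_codes = [name_to_code[n] for n in ("forest", "shrubland", "grassland")]
    codes[~anthro] = rng.choice(natural_codes, size=int((~anthro).sum()))
    anthro_names = list(_ANTHRO_MIX)
    weights = np.array([_ANTHRO_MIX[n] for n in anthro_names])
    codes[anthro] = rng.choice(
        [name_to_code[n] for n in anthro_names], size=int(anthro.sum()), p=weights / weights.sum()
    )
    return Raster(spec, codes, kind="categorical", categories=dict(LANDUSE_CODES))


def generate_dem(
    spec: GridSpec,
    relief_m: float = 1000.0,
    base_m: float = 500.0,
    scale_km: float = 20.0,
    seed: int = 0,
) -> Raster:
    """Smooth synthetic elevation surface (metres)."""
    rng = _rng(seed, STAGE_DEM)
    z = _smooth_field(spec, scale_km, rng)
    return Raster(spec, base_m + relief_m * (z - z.min()) / max(np.ptp(z), 1e-12))


def generate_villages(
    spec: GridSpec,
    intensity_per_km2: float = 0.01,
    pop_log_mean: float = 5.0,
    pop_log_sd: float = 1.2,
    seed: int = 0,
) -> PointSet:
    """Homogeneous Poisson village pattern with log-normal populations.

    Populations are drawn log-normally (median ``exp(pop_log_mean)`` ≈ 148
    inhabitants at the default, a right tail typical of settlement-size
    data), rounded and floored at 1.
    """
    if intensity_per_km2 < 0:
        raise ValueError("intensity must be non-negative")
    rng = _rng(seed, STAGE_VILLAGES)
    n = rng.poisson(intensity_per_km2 * spec.total_area_km2)
    x = spec.origin_x_km + rng.uniform(0, spec.n_cols * spec.cell_size_km, n)
    y = spec.origin_y_km + rng.uniform(0, spec.n_rows * spec.cell_size_km, n)
    pop = np.maximum(1, np.round(rng.lognormal(pop_log_mean, pop_log_sd, n))).astype(int)
    return PointSet(np.column_stack([x, y]) if n else np.empty((0, 2)), {"population": pop})


def true_suitability(
    env_layers: list[Raster],
    truth: TruthParams,
    categorical_layers: dict[str, Raster] | None = None,
) -> Raster:
    """Evaluate the generating suitability surface, cellwise logistic."""
    if len(truth.env_coefficients) != len(env_layers):
        raise ValueError(
            f"{len(truth.env_coefficients)} coefficients for {len(env_layers)} layers"
        )
    spec = env_layers[0].spec if env_layers else None
    eta = None
    for beta, layer in zip(truth.env_coefficients, env_layers):
        if layer.spec != spec:
            raise ValueError("environmental layers on different grids")
        eta = beta * layer.values if eta is None else eta + beta * layer.values
    if categorical_layers:
        for name, effects in truth.categorical_effects.items():
            layer = categorical_layers[name]
            if spec is None:
                spec = layer.spec
            lut = np.vectorize(lambda c: effects.get(int(c), 0.0))
            add = lut(layer.values)
            eta = add if eta is None else eta + add
    if eta is None:
        if spec is None:
            raise ValueError("no layers supplied")
        eta = np.zeros(spec.shape)
    prob = 1.0 / (1.0 + np.exp(-(truth.intercept + eta)))
    return Raster(spec, prob)


def sample_occurrences(
    suitability: Raster, n: int, seed: int = 0, species: str = "synthetic_sp"
) -> PointSet:
    """Draw occurrence points with cell probability ∝ suitability.

    Each drawn cell receives a point uniformly within it. Sampling is with
    replacement across draws (a cell can yield several records).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    spec = suitability.spec
    if n == 0:
        return PointSet(np.empty((0, 2)), {"species": np.array([], dtype=object)})
    w = suitability.values.ravel().astype(float)
    w = np.where(w > 0, w, 0.0)
    if w.sum() == 0:
        raise ValueError("cannot sample occurrences from an all-zero suitability map")
    rng = _rng(seed, STAGE_OCCURRENCES)
    flat = rng.choice(w.size, size=n, p=w / w.sum())
    i, j = np.unravel_index(flat, spec.shape)
    x = spec.origin_x_km + (j + rng.uniform(0, 1, n)) * spec.cell_size_km
    y = spec.origin_y_km + (i + rng.uniform(0, 1, n)) * spec.cell_size_km
    return PointSet(
        np.column_stack([x, y]),
        {
            "species": np.array([species] * n, dtype=object),
            "coord_error_km": np.zeros(n),
        },
    )


def generate_bundle(
    spec: GridSpec | None = None,
    n_env_layers: int = 19,
    autocorr_scale_km: float = 10.0,
    anthropogenic_fraction: float = 0.3,
    landuse_clustering_km: float = 5.0,
    village_intensity_per_km2: float = 0.01,
    n_occurrences: int = 200,
    truth: TruthParams | None = None,
    seed: int = 0,
) -> LandscapeBundle:
    """Generate a full synthetic study system from one master seed.

    Defaults mirror the field setting the pipeline emulates: 19
    continuous bioclimatic-style layers at ~1×1 km resolution on a
    100×100 km window, a ~30% disturbed land-use mosaic, ~1 village per
    100 km², and 200 verified occurrence records of one species with a
    strong (|β| = 2) environmental signal.
    """
    if spec is None:
        spec = GridSpec(100, 100, 1.0)
    if truth is None:
        # default truth: a restricted-range habitat specialist — strong
        # (|β| = 2) response to four environmental axes, low baseline
        # prevalence (~10% of the landscape occupied)
        coeffs = tuple([2.0, -2.0, 2.0, -2.0] + [0.0] * (n_env_layers - 4))[:n_env_layers]
        truth = TruthParams(intercept=-5.0, env_coefficients=coeffs)
    env = generate_env_layers(spec, n_env_layers, autocorr_scale_km, seed)
    soil = generate_categorical_layer(spec, 4, 15.0, seed, STAGE_SOIL)
    vegetation = generate_categorical_layer(spec, 5, 12.0, seed, STAGE_VEGETATION)
    ecoregion = generate_categorical_layer(spec, 3, 30.0, seed, STAGE_ECOREGION)
    landuse = generate_landuse(spec, anthropogenic_fraction, landuse_clustering_km, seed)
    dem = generate_dem(spec, seed=seed)
    villages = generate_villages(spec, village_intensity_per_km2, seed=seed)
    suit = true_suitability(env, truth)
    true_range = BinaryMask(spec, suit.values >= truth.occupancy_threshold)
    occurrences = sample_occurrences(suit, n_occurrences, seed)
    return LandscapeBundle(
        spec=spec,
        env_layers=env,
        soil=soil,
        vegetation=vegetation,
        ecoregion=ecoregion,
        landuse=landuse,
        dem=dem,
        villages=villages,
        truth=truth,
        true_suitability=suit,
        true_range=true_range,
        seed=seed,
        occurrences=occurrences,
    )
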