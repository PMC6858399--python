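# Methods

## Geometry and conventions

All computation happens on uniform planar grids in km units: origin at
the lower-left corner, x east, y north, 0-based cell indices with row 0
at the bottom, half-open extents `[origin, origin + n·cell)`. The
working resolution mirrors the ~1×1 km cells typical of 30-arc-second
environmental data; geographic reprojection is deliberately out of
scope — synthetic landscapes are generated directly in planar km, so no
assessed quantity depends on geodesy. Nodata cells are excluded from
standardisation, model fitting, prediction and every area sum.

Buffering (`buffer_mask`) uses exact centre-to-centre Euclidean distance
with an inclusive comparison, computed via the Euclidean distance
transform; it is monotone in distance and the identity at distance 0. A
relative guard of 1 + 1e-12 on the radius keeps exactly-representable
distances (e.g. 2.0 km = 200 cells of 0.01 km) inside the mask despite
float rounding. Patch delimitation defaults to 8-connectivity (queen):
at 1-km resolution a diagonal gap does not make habitat discontinuous;
4-connectivity remains available everywhere through configuration.
Convex hulls and polygon point-in-tests use shapely; degenerate hulls
(collinear or duplicated points) have area 0 by convention.

## Synthetic study systems

The generator produces complete assessment inputs with a known
species–environment truth, so each downstream statistic can be validated
against ground truth rather than against another implementation.

- **Environmental layers.** Real bioclimatic stacks are families of
  temperature/precipitation summaries of a few underlying climatic
  gradients, hence strongly collinear — that collinearity is the reason
  a two-axis PCA reduction is viable at all. The generator therefore
  mixes `n_latent` (default 2) shared Gaussian-smoothed random fields
  into each of the 19 layers with random unit weights, plus a 0.3-weight
  independent smooth component, then re-standardises. Autocorrelation is
  set by the smoothing bandwidth (default 10 km). With independent
  layers instead, the two unsupervised PCA axes cannot span a
  multi-layer truth direction and no model family could recover the
  signal — a generator artefact, not a property of real data.
- **Truth.** Suitability is cellwise
  `logistic(intercept + Σ βk·envk + categorical effects)`. The default
  truth is a restricted-range habitat specialist: intercept −5 and
  coefficients (2, −2, 2, −2, 0, …), giving ≈10% landscape occupancy at
  the 0.5 occupancy threshold and a recoverable signal consistent with
  the AUC range (0.81–0.98) reported for well-performing SDMs of
  range-restricted species. `|β| = 2` is the "strong signal" condition
  used throughout the recovery tests.
- **Land use.** A smoothed field thresholded at its empirical
  `1 − f` quantile gives a spatially clustered disturbed fraction that
  matches `f` up to ties; disturbed cells are split crop/urban/water/
  bare (0.55/0.20/0.10/0.15), natural cells forest/shrubland/grassland.
- **Villages.** Homogeneous Poisson counts (default 0.01 km⁻², ~1 per
  100 km²) with uniform positions; populations log-normal
  (`exp(N(5, 1.2²))`, median ≈ 148, floored at 1) — the heavy right
  tail of settlement-size data; only the >100 cutoff matters downstream.
- **Occurrences.** Cells drawn with probability proportional to true
  suitability (with replacement), a point placed uniformly inside each
  drawn cell; default 200 records. Per-record coordinate error is
  carried as an attribute but used by no formula.
- **Seeding.** One master seed; stage `k` uses
  `SeedSequence([master, STAGE_k])`, so any component regenerates
  independently and bitwise-identically.

What the generator does **not** emulate: sampling bias along roads,
spatial clustering of collectors, temporal turnover, label noise in
occurrence identifications, and raster misalignment. Passing recovery
tests therefore demonstrates correctness of the estimators under clean
sampling, not robustness to survey artefacts in real data.

## SDM

The model family is L2-regularised logistic presence/background
discrimination on raster cells — a minimal, deterministic Maxent-style
analogue, not a reimplementation of any specific SDM package (published
assessments rarely state the algorithm behind their suitability maps;
this family is a documented stand-in chosen to exercise every
downstream statistic). Cells containing ≥1 record are the presence
units; each of the (default 10) replicates draws its own uniform
background sample without replacement from non-presence cells (default
size 10× presences, capped at 20% of valid cells, never below the
presence count) and fits `LogisticRegression` with `C = 1/regularization`;
the suitability surface is the cellwise mean predicted probability.
Because the penalised objective is strictly convex for any positive
regularisation, no singular-fit fallback is needed. Feature space: the
two leading PCA axes of the standardised continuous layers (axis sign
fixed so the largest-magnitude loading is positive; constant layers are
dropped with a warning, and fewer than two usable layers is an error)
plus drop-first indicators for categorical layers.

AUC is concordance (Mann–Whitney, ties 0.5); sensitivity uses the ≥
rule at the threshold, TSS = sensitivity + specificity − 1. Whether a
published AUC was computed on training or held-out data is usually
unstated; the package computes both (training evaluation in the
assessment record, held-out evaluation in the validation suite).
Binarisation scans the observed calibration scores and takes the
max-TSS threshold, breaking ties toward the **largest** threshold (the
smaller, more precautionary range). Both filters only remove cells: a
predicted patch survives the patch filter iff some cell centre lies in
or on the occurrence convex hull (degenerate hulls fall back to keeping
patches containing occurrence cells, with a warning), and the expert
mask keeps cells whose centres are covered by any polygon — an empty
polygon list therefore empties the range.

## Range metrics

AOO uses the IUCN-standard 2-km overlay even though the working raster
is 1 km (published AOO values are multiples of 4 km², consistent with
this convention). The overlay is aligned to the raster origin; the
IUCN's recommended minimisation over grid offsets is not implemented —
an explicit limitation. EOO is the convex-hull area of occupied-cell
centres floored at AOO; note the flooring means a dense interior fill
can raise EOO through AOO even though the hull is unchanged. Elevation
range is the min/max DEM value over occupied non-nodata cells.

## Fragmentation (RA_LQH)

The LQH mask is built from the *whole-landscape* disturbance footprint:
anthropogenic cells are dilated by `buffer_km` (default 2, the
expert-recommended threat-influence distance; the plausible range
extends to ~10 km and the parameter is exposed) **before** intersecting
with the range, so disturbance just outside the range contaminates edge
cells. The denominator of RA_LQH sums over the species' own filtered
binary range — the ratio is the relative abundance of the species in
LQH, which must normalise over its predicted population, not the study
grid. Numerator and denominator are computed cellwise
(Σ cell_area · p); the per-patch tables aggregate the same sums by
connected component and agree with the cellwise view to 1e-9 relative —
an internal oracle asserted in the tests. Severe fragmentation is a
strict `> 50%` comparison; 50.0 exactly is not severe.

## Locations

Villages with population strictly above 100 ("above 100 inhabitants"
read literally; the cutoff is configurable) whose 2.5-km disk reaches
any occupied cell centre are retained; two villages merge iff their
centre distance is strictly below 2× the radius (tangent disks share no
interior, hence no merge), closed transitively by union-find. Counts
are exact and never rounded. The count is *not* monotone in the
population cutoff: raising it can delete a bridging village and split
one agglomeration into several; only the retained village set shrinks
monotonically. The count is monotone nonincreasing in the radius.

## Assessment assembly

`run_assessment` chains the stages deterministically under one seed
(the calibration background for thresholding uses a stream separated
from the fit stream by a fixed offset), logs one structured line per
stage, and records provenance: seed, threshold, filters applied, and
SHA-256 digests (truncated) of every input array. Screens are strict
`<` on 20,000 / 2,000 km². Errors propagate wrapped with the stage
name.

## Problem sizes and numerical choices

Validation runs use 100×100 km landscapes at 1-km cells (60×60 for
unit-level fixtures), 200 occurrence records, 10 background replicates,
and 20 seeds for sign-recovery — sizes at which every recovered
quantity is stable while the full suite stays fast. Constant-layer
detection uses a relative spread tolerance (1e-9 scaled by the layer
mean) because an exactly-constant layer still shows ~1e-14 float spread
in its sample standard deviation. PCA eigenvalues are reported from the
ddof-0 covariance of the standardised matrix so the trace equals the
number of retained layers exactly. The land-use fraction is exact up to
quantile ties; the village-merge and buffer comparisons are strict/
inclusive respectively, as stated above.

## Known limitations

Planar geometry only; no alpha-hull EOO; no AOO grid-offset
minimisation; no dispersal or population-viability modelling behind the
fragmentation flag; the SDM family is a stand-in (no hinge/product
features, no cross-algorithm model selection); Red List categories are
not assigned — the package stops at the quantitative criterion-B
evidence (metrics, flags, screens) that an assessor would combine with
threat and population context.
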