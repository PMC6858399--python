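"""Presence/background species distribution modelling.

The model family is regularised logistic presence-vs-background
discrimination on raster cells — a minimal Maxent-style analogue that is
deterministic given a seed. Continuous environmental layers are first
reduced to the two leading principal-component axes (standardised
z-scores, PCA over non-nodata cells); categorical layers enter as
indicator features. Replicates vary only the background sample; the
suitability surface is the cellwise mean predicted probability across
replicates.

Binarisation picks the calibration-score threshold maximising the True
Skill Statistic, and two precautionary filters shrink the binary range:
removal of predicted patches wholly outside the minimum convex polygon
of the occurrence records, and intersection with expert range polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .grid import BinaryMask, PointSet, Raster, connected_components

__all__ = [
    "FeatureSpace",
    "SdmEvaluation",
    "RangeMap",
    "SdmClassifier",
    "pca_reduce",
    "fit_sdm",
    "evaluate_sdm",
    "binarize_range",
    "filter_patches",
    "apply_expert_mask",
]


@dataclass
class FeatureSpace:
    """Fitted mapping from raw layers to model features (2 PCA axes + indicators)."""

    pca_loadings: np.ndarray  # (2, n_layers) rows are axes, orthonormal
    layer_means: np.ndarray
    layer_sds: np.ndarray
    explained_variance: np.ndarray  # all eigenvalues of the standardized covariance
    kept_layers: np.ndarray  # indices of non-degenerate input layers
    categorical_encoding: dict[str, list[int]] = field(default_factory=dict)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


@dataclass
class SdmEvaluation:
    auc: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class RangeMap:
    """Binary predicted range with its provenance (threshold + filters)."""

    mask: BinaryMask
    threshold_used: float
    filters_applied: list[str] = field(default_factory=list)


def pca_reduce(env_layers: list[Raster]) -> tuple[FeatureSpace, list[Raster]]:
    """Standardise continuous layers and project onto the two leading PCA axes.

    Constant (zero-variance) layers are dropped with a warning; fewer than
    two usable layers is an error. The sign of each axis is fixed so that
    its largest-magnitude loading is positive. Nodata cells (in any layer)
    are excluded from the fit and marked nodata in the score rasters.
    """
    if len(env_layers) < 2:
        raise ValueError("need at least 2 environmental layers for PCA reduction")
    spec = env_layers[0].spec
    if any(l.spec != spec for l in env_layers):
        raise ValueError("environmental layers on different grids")
    valid = np.ones(spec.shape, dtype=bool)
    for l in env_layers:
        valid &= l.valid_mask()
    if not valid.any():
        raise ValueError("no cell is valid across all layers")

    stack = np.stack([l.values[valid] for l in env_layers], axis=1)  # (n_cells, n_layers)
    sds = stack.std(axis=0)
    # relative tolerance: a layer is constant when its spread is float noise
    kept = np.flatnonzero(sds > 1e-9 * (1.0 + np.abs(stack.mean(axis=0))))
    if len(kept) < len(env_layers):
        warnings.warn(f"dropping {len(env_layers) - len(kept)} constant layer(s) before PCA")
    if len(kept) < 2:
        raise ValueError("fewer than 2 non-degenerate layers; PCA to 2 axes impossible")
    stack = stack[:, kept]
    means = stack.mean(axis=0)
    sds = stack.std(axis=0)
    z = (stack - means) / sds

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.copy()
    # sign convention: largest-magnitude loading of each axis is positive
    for a in range(2):
        k = np.argmax(np.abs(loadings[a]))
        if loadings[a, k] < 0:
            loadings[a] = -loadings[a]
            scores[:, a] = -scores[:, a]

    # full eigen-spectrum for trace/explained-variance reporting; bias=True
    # matches the ddof-0 standardisation, so the trace equals n_kept exactly
    full_ev = np.linalg.eigvalsh(np.cov(z, rowvar=False, bias=True))[::-1]

    fs = FeatureSpace(
        pca_loadings=loadings,
        layer_means=means,
        layer_sds=sds,
        explained_variance=full_ev,
        kept_layers=kept,
    )
    out = []
    for a in range(2):
        vals = np.full(spec.shape, env_layers[0].nodata)
        vals[valid] = scores[:, a]
        out.append(Raster(spec, vals, nodata=env_layers[0].nodata))
    return fs, out


def _cell_features(
    pc_rasters: list[Raster],
    categorical_rasters: dict[str, Raster] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix over valid cells; returns (X, valid_mask, feature_names)."""
    spec = pc_rasters[0].spec
    valid = np.ones(spec.shape, dtype=bool)
    for r in pc_rasters:
        valid &= r.valid_mask()
    cols = [r.values[valid] for r in pc_rasters]
    names = [f"pc{a + 1}" for a in range(len(pc_rasters))]
    if categorical_rasters:
        for lname, r in categorical_rasters.items():
            if r.spec != spec:
                raise ValueError(f"categorical layer {lname!r} on a different grid")
            codes = sorted(int(c) for c in np.unique(r.values[r.valid_mask()]))
            for c in codes[1:]:  # drop-first indicator coding
                cols.append((r.values[valid] == c).astype(float))
                names.append(f"{lname}={c}")
    return np.column_stack(cols), valid, names


class SdmClassifier(BaseEstimator):
    """Regularised logistic presence/background SDM over raster cells.

    Parameters
    ----------
    n_background : int or None
        Background cells per replicate; ``None`` uses 10× the number of
        presence cells, capped at 20% of valid cells.
    n_replicates : int
        Number of background resamples averaged into the suitability map.
    regularization : float
        L2 penalty strength (inverse of sklearn's ``C``).
    random_state : int
        Seed for background sampling.

    Fitted attributes (trailing underscore): ``replicate_weights_`` (one
    ``(intercept, coefs)`` row per replicate), ``feature_names_``,
    ``suitability_`` (a :class:`~critb.grid.Raster` of mean predicted
    probability), ``presence_cells_``.
    """

    def __init__(
        self,
        n_background: int | None = None,
        n_replicates: int = 10,
        regularization: float = 1.0,
        random_state: int = 0,
    ):
        self.n_background = n_background
        self.n_replicates = n_replicates
        self.regularization = regularization
        self.random_state = random_state

    def fit(
        self,
        occurrences: PointSet,
        pc_rasters: list[Raster],
        categorical_rasters: dict[str, Raster] | None = None,
    ) -> "SdmClassifier":
        if len(occurrences) < 5:
            raise ValueError("need at least 5 occurrence records")
        spec = pc_rasters[0].spec
        X, valid, names = _cell_features(pc_rasters, categorical_rasters)
        i, j = spec.point_to_cell(occurrences.x, occurrences.y)  # raises if outside grid
        flat_valid = np.flatnonzero(valid.ravel())
        pos_in_valid = -np.ones(valid.size, dtype=int)
        pos_in_valid[flat_valid] = np.arange(len(flat_valid))
        occ_flat = np.unique(i * spec.n_cols + j)
        if np.any(pos_in_valid[occ_flat] < 0):
            raise ValueError("occurrence record falls on a nodata cell")
        presence_idx = pos_in_valid[occ_flat]

        n_cells = X.shape[0]
        n_presence = len(presence_idx)
        n_bg = self.n_background
        if n_bg is None:
            n_bg = min(10 * n_presence, int(0.2 * n_cells))
        n_bg = max(n_bg, n_presence)
        candidates = np.setdiff1d(np.arange(n_cells), presence_idx)
        n_bg = min(n_bg, len(candidates))
        if n_bg == 0:
            raise ValueError("no background cells available")

        rng = np.random.default_rng(self.random_state)
        C = 1.0 / max(self.regularization, 1e-12)
        weights, prob_sum = [], np.zeros(n_cells)
        for _ in range(self.n_replicates):
            bg = rng.choice(candidates, size=n_bg, replace=False)
            rows = np.concatenate([presence_idx, bg])
            y = np.concatenate([np.ones(n_presence), np.zeros(n_bg)])
            clf = LogisticRegression(C=C, max_iter=2000)
            clf.fit(X[rows], y)
            weights.append(np.concatenate([clf.intercept_, clf.coef_.ravel()]))
            prob_sum += clf.predict_proba(X)[:, 1]

        self.replicate_weights_ = np.array(weights)
        self.feature_names_ = names
        self.presence_cells_ = occ_flat
        vals = np.full(spec.shape, pc_rasters[0].nodata)
        vals[valid] = prob_sum / self.n_replicates
        self.suitability_ = Raster(spec, vals, nodata=pc_rasters[0].nodata)
        return self

    @property
    def mean_weights_(self) -> np.ndarray:
        return self.replicate_weights_.mean(axis=0)


def fit_sdm(
    occurrences: PointSet,
    pc_rasters: list[Raster],
    categorical_rasters: dict[str, Raster] | None = None,
    n_background: int | None = None,
    n_replicates: int = 10,
    regularization: float = 1.0,
    seed: int = 0,
) -> tuple[SdmClassifier, Raster]:
    """Functional wrapper over :class:`SdmClassifier`; returns (model, suitability)."""
    model = SdmClassifier(
        n_background=n_background,
        n_replicates=n_replicates,
        regularization=regularization,
        random_state=seed,
    ).fit(occurrences, pc_rasters, categorical_rasters)
    return model, model.suitability_


def _scores_at(suitability: Raster, points: PointSet) -> np.ndarray:
    i, j = suitability.spec.point_to_cell(points.x, points.y)
    return suitability.values[i, j]


def evaluate_sdm(
    suitability: Raster,
    test_presences: PointSet,
    test_background: PointSet,
    threshold: float,
) -> SdmEvaluation:
    """AUC (Mann–Whitney, ties 0.5) and TSS at ``threshold`` (presence rule: >=)."""
    if len(test_presences) == 0 or len(test_background) == 0:
        raise ValueError("test presence and background sets must be nonempty")
    sp = _scores_at(suitability, test_presences)
    sb = _scores_at(suitability, test_background)
    y = np.concatenate([np.ones(len(sp)), np.zeros(len(sb))])
    auc = float(roc_auc_score(y, np.concatenate([sp, sb])))
    sens = float(np.mean(sp >= threshold))
    spec_ = float(np.mean(sb < threshold))
    return SdmEvaluation(
        auc=auc, tss=sens + spec_ - 1.0, threshold=float(threshold),
        sensitivity=sens, specificity=spec_,
    )


def binarize_range(
    suitability: Raster, presences: PointSet, background: PointSet
) -> RangeMap:
    """Threshold the suitability map at the max-TSS calibration score.

    Candidate thresholds are the observed calibration scores; ties in TSS
    are broken toward the largest threshold (the more conservative range).
    """
    sp = _scores_at(suitability, presences)
    sb = _scores_at(suitability, background)
    cand = np.unique(np.concatenate([sp, sb]))
    if len(cand) == 1:
        raise ValueError("degenerate model: all calibration scores identical")
    tss = np.array([np.mean(sp >= t) + np.mean(sb < t) - 1.0 for t in cand])
    best = cand[np.flatnonzero(tss == tss.max())].max()
    mask = BinaryMask(
        suitability.spec, (suitability.values >= best) & suitability.valid_mask()
    )
    return RangeMap(mask=mask, threshold_used=float(best))


def filter_patches(
    range_map: RangeMap, occurrences: PointSet, connectivity: int = 8
) -> RangeMap:
    """Drop predicted patches wholly outside the occurrence convex hull.

    The "original distribution polygon" is the minimum convex polygon of
    the occurrence records; a patch survives iff at least one of its cell
    centres lies inside or on that hull. With fewer than 3 non-collinear
    records the hull is degenerate: the fallback keeps only patches
    containing at least one occurrence cell.
    """
    mask = range_map.mask
    if not mask.cells.any():
        return RangeMap(mask, range_map.threshold_used, range_map.filters_applied + ["patch_filter"])
    patches = connected_components(mask, connectivity)
    hull = MultiPoint(occurrences.xy).convex_hull
    X, Y = mask.spec.cell_centers()
    if hull.geom_type == "Polygon":
        inside = shapely.covers(hull, shapely.points(np.column_stack([X.ravel(), Y.ravel()])))
        inside = inside.reshape(mask.spec.shape)
    else:
        warnings.warn(
            "occurrence hull is degenerate; keeping only patches containing occurrence cells"
        )
        inside = np.zeros(mask.spec.shape, dtype=bool)
        i, j = mask.spec.point_to_cell(occurrences.x, occurrences.y)
        inside[i, j] = True
    keep_ids = np.unique(patches.labels[inside & mask.cells])
    keep_ids = keep_ids[keep_ids > 0]
    new_cells = np.isin(patches.labels, keep_ids)
    return RangeMap(
        BinaryMask(mask.spec, new_cells),
        range_map.threshold_used,
        range_map.filters_applied + ["patch_filter"],
    )


def apply_expert_mask(range_map: RangeMap, expert_polygons: list) -> RangeMap:
    """Intersect the range with expert-drawn polygons (cell-centre rule).

    A cell survives iff its centre falls inside or on any polygon. An
    empty polygon list empties the mask (vacuous intersection).
    """
    mask = range_map.mask
    spec = mask.spec
    inside = np.zeros(spec.shape, dtype=bool)
    if expert_polygons:
        X, Y = spec.cell_centers()
        pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
        for poly in expert_polygons:
            inside |= shapely.covers(poly, pts).reshape(spec.shape)
    return RangeMap(
        BinaryMask(spec, mask.cells & inside),
        range_map.threshold_used,
        range_map.filters_applied + ["expert_mask"],
    )
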