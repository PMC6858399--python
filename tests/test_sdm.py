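"""SDM stage: PCA reduction, fitting, evaluation, binarisation, filters."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from shapely.geometry import Polygon

from critb import (
    BinaryMask,
    GridSpec,
    PointSet,
    Raster,
    apply_expert_mask,
    binarize_range,
    evaluate_sdm,
    filter_patches,
    fit_sdm,
    pca_reduce,
)
from critb.landscape import generate_env_layers, sample_occurrences
from critb.sdm import RangeMap


class TestPcaReduce:
    def test_near_duplicate_layers_load_on_one_axis(self):
        spec = GridSpec(40, 40)
        base = generate_env_layers(spec, 1, 5.0, seed=1)[0]
        rng = np.random.default_rng(2)
        layers = [
            Raster(spec, base.values + 1e-3 * rng.standard_normal(spec.shape))
            for _ in range(19)
        ]
        fs, _ = pca_reduce(layers)
        assert fs.explained_variance_ratio[0] > 0.99

    def test_scores_are_uncorrelated(self):
        layers = generate_env_layers(GridSpec(50, 50), 5, 4.0, seed=3)
        _, (pc1, pc2) = pca_reduce(layers)
        r = np.corrcoef(pc1.values.ravel(), pc2.values.ravel())[0, 1]
        assert abs(r) < 0.01

    def test_two_layers_preserve_total_variance(self):
        layers = generate_env_layers(GridSpec(30, 30), 2, 3.0, seed=4)
        fs, _ = pca_reduce(layers)
        assert fs.explained_variance.sum() == pytest.approx(2.0, abs=1e-6)

    def test_sign_convention_largest_loading_positive(self):
        layers = generate_env_layers(GridSpec(30, 30), 4, 3.0, seed=5)
        fs, _ = pca_reduce(layers)
        for axis in fs.pca_loadings:
            assert axis[np.argmax(np.abs(axis))] > 0

    def test_constant_layer_dropped_with_warning(self):
        spec = GridSpec(20, 20)
        layers = generate_env_layers(spec, 2, 2.0, seed=6)
        layers.append(Raster(spec, np.full(spec.shape, 3.3)))
        with pytest.warns(UserWarning, match="constant"):
            fs, _ = pca_reduce(layers)
        assert len(fs.kept_layers) == 2

    def test_fewer_than_two_usable_layers_rejected(self):
        spec = GridSpec(10, 10)
        flat = Raster(spec, np.zeros(spec.shape))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                pca_reduce([flat, generate_env_layers(spec, 1, 0.0, seed=1)[0]])


class TestFitSdm:
    def test_suitability_tracks_occurrence_gradient(self):
        spec = GridSpec(50, 50)
        layers = generate_env_layers(spec, 3, 6.0, seed=7)
        _, pcs = pca_reduce(layers)
        # occurrences concentrated where PC1 is high
        p = 1 / (1 + np.exp(-3 * pcs[0].values))
        occ = sample_occurrences(Raster(spec, p / p.max()), 150, seed=8)
        _, suit = fit_sdm(occ, pcs, n_replicates=5, seed=8)
        rho = spearmanr(suit.values.ravel(), pcs[0].values.ravel()).statistic
        assert rho > 0.5
        assert np.all((suit.values >= 0) & (suit.values <= 1))

    def test_too_few_occurrences_rejected(self):
        spec = GridSpec(10, 10)
        _, pcs = pca_reduce(generate_env_layers(spec, 2, 1.0, seed=1))
        with pytest.raises(ValueError, match="at least 5"):
            fit_sdm(PointSet([(1, 1), (2, 2)] * 2), pcs)

    def test_occurrences_outside_grid_rejected(self):
        spec = GridSpec(10, 10)
        _, pcs = pca_reduce(generate_env_layers(spec, 2, 1.0, seed=1))
        pts = PointSet([(1, 1), (2, 2), (3, 3), (4, 4), (50, 50)])
        with pytest.raises(ValueError, match="outside"):
            fit_sdm(pts, pcs)

    def test_deterministic_given_seed(self, small_bundle):
        _, pcs = pca_reduce(small_bundle.env_layers)
        _, s1 = fit_sdm(small_bundle.occurrences, pcs, n_replicates=3, seed=9)
        _, s2 = fit_sdm(small_bundle.occurrences, pcs, n_replicates=3, seed=9)
        assert np.array_equal(s1.values, s2.values)


def scored_map(scores_by_cell):
    """1-row raster whose columns carry the given suitability scores."""
    vals = np.array([scores_by_cell])
    return Raster(GridSpec(1, len(scores_by_cell)), vals)


def pts_at_cols(cols):
    return PointSet([(c + 0.5, 0.5) for c in cols])


class TestEvaluateSdm:
    def test_perfect_separation_gives_auc_one(self):
        suit = scored_map([0.9, 0.8, 0.7, 0.1])
        ev = evaluate_sdm(suit, pts_at_cols([0, 1]), pts_at_cols([2, 3]), 0.75)
        assert ev.auc == 1.0

    def test_tie_counts_half(self):
        # presences 0.9, 0.4; background 0.4, 0.1 -> 3 concordant + 1 tie over 4
        suit = scored_map([0.9, 0.4, 0.4, 0.1])
        ev = evaluate_sdm(suit, pts_at_cols([0, 1]), pts_at_cols([2, 3]), 0.4)
        assert ev.auc == pytest.approx(0.875)
        # threshold 0.4 with >= rule: sens 1.0, spec 0.5, TSS 0.5
        assert ev.sensitivity == 1.0
        assert ev.specificity == 0.5
        assert ev.tss == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_transform(self):
        raw = [0.9, 0.4, 0.35, 0.1, 0.7, 0.2]
        ev1 = evaluate_sdm(scored_map(raw), pts_at_cols([0, 1, 4]), pts_at_cols([2, 3, 5]), 0.5)
        squashed = [v**3 for v in raw]
        ev2 = evaluate_sdm(scored_map(squashed), pts_at_cols([0, 1, 4]), pts_at_cols([2, 3, 5]), 0.5)
        assert ev1.auc == pytest.approx(ev2.auc)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_sdm(scored_map([0.5, 0.5]), pts_at_cols([]), pts_at_cols([1]), 0.5)


class TestBinarizeRange:
    def test_max_tss_threshold_with_largest_tie(self):
        suit = scored_map([0.8, 0.9, 0.1, 0.2])
        rm = binarize_range(suit, pts_at_cols([0, 1]), pts_at_cols([2, 3]))
        # thresholds 0.8 and anything in (0.2, 0.8] give TSS 1; largest candidate wins
        assert rm.threshold_used == pytest.approx(0.8)
        assert rm.mask.cells[0].tolist() == [True, True, False, False]

    def test_raising_threshold_never_adds_cells(self):
        suit = scored_map([0.1, 0.3, 0.5, 0.7, 0.9])
        low = BinaryMask(suit.spec, suit.values >= 0.3)
        high = BinaryMask(suit.spec, suit.values >= 0.7)
        assert np.all(low.cells[high.cells])

    def test_degenerate_scores_rejected(self):
        suit = scored_map([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="degenerate"):
            binarize_range(suit, pts_at_cols([0, 1]), pts_at_cols([2, 3]))


def range_of(cells, spec):
    m = np.zeros(spec.shape, dtype=bool)
    for i, j in cells:
        m[i, j] = True
    return RangeMap(BinaryMask(spec, m), threshold_used=0.5)


class TestFilterPatches:
    def test_patch_outside_hull_removed(self):
        spec = GridSpec(10, 10)
        main = [(i, j) for i in range(0, 4) for j in range(0, 4)]
        island = [(8, 8), (8, 9)]
        rm = range_of(main + island, spec)
        occ = PointSet([(0.5, 0.5), (3.5, 0.5), (0.5, 3.5), (3.5, 3.5)])
        out = filter_patches(rm, occ)
        assert out.mask.n_true == len(main)
        assert not out.mask.cells[8, 8]
        assert "patch_filter" in out.filters_applied

    def test_single_patch_with_occurrences_unchanged(self, spec10):
        rm = range_of([(1, 1), (1, 2), (2, 1)], spec10)
        occ = PointSet([(1.5, 1.5), (2.5, 1.5), (1.5, 2.5)])
        assert filter_patches(rm, occ).mask.n_true == 3

    def test_empty_mask_stays_empty(self, spec10):
        rm = range_of([], spec10)
        out = filter_patches(rm, PointSet([(1, 1), (2, 2), (1, 2)]))
        assert out.mask.n_true == 0

    def test_collinear_occurrences_fall_back_with_warning(self, spec10):
        rm = range_of([(1, 1), (5, 5)], spec10)
        occ = PointSet([(1.5, 1.5), (2.5, 2.5), (3.5, 3.5)])
        with pytest.warns(UserWarning, match="degenerate"):
            out = filter_patches(rm, occ)
        assert out.mask.cells[1, 1] and not out.mask.cells[5, 5]


class TestApplyExpertMask:
    def test_whole_grid_polygon_is_identity(self, spec10):
        rm = range_of([(2, 2), (7, 7)], spec10)
        out = apply_expert_mask(rm, [Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])])
        assert np.array_equal(out.mask.cells, rm.mask.cells)

    def test_empty_polygon_list_empties_mask(self, spec10):
        rm = range_of([(2, 2)], spec10)
        assert apply_expert_mask(rm, []).mask.n_true == 0

    def test_half_plane_keeps_half_the_cells(self, spec10):
        rm = range_of([(i, j) for i in range(10) for j in range(10)], spec10)
        west = Polygon([(0, 0), (5, 0), (5, 10), (0, 10)])
        assert apply_expert_mask(rm, [west]).mask.n_true == 50

    def test_filtering_never_adds_cells(self, spec10):
        rm = range_of([(i, j) for i in range(10) for j in range(3)], spec10)
        out = apply_expert_mask(rm, [Polygon([(0, 0), (4, 0), (4, 4), (0, 4)])])
        assert out.mask.n_true <= rm.mask.n_true
        assert np.all(rm.mask.cells[out.mask.cells])
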