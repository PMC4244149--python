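"""Generator contracts: determinism, correlation control, scenario structure."""

import numpy as np
import pytest
from scipy import stats

from nichecmp import synthetic
from nichecmp.errors import ArgumentError, GeometryError, SamplingError
from nichecmp.synthetic import (
    SpeciesTruth,
    generate_landscape,
    generate_remnants,
    generate_scenario,
    make_biome_masks,
    sample_occurrences,
)


class TestGenerateLandscape:
    def test_seeded_determinism(self):
        a = generate_landscape(32, 32, 5, smoothness=0.3, correlation=0.0, seed=7)
        b = generate_landscape(32, 32, 5, smoothness=0.3, correlation=0.0, seed=7)
        assert np.array_equal(a.values, b.values)
        assert a.layer_names == b.layer_names

    def test_different_seeds_differ(self):
        a = generate_landscape(32, 32, 2, seed=1)
        b = generate_landscape(32, 32, 2, seed=2)
        assert not np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("target", [0.9, 0.0, -0.5])
    def test_realized_interlayer_correlation(self, target):
        grid = generate_landscape(32, 32, 2, smoothness=0.3, correlation=target, seed=1)
        r = np.corrcoef(grid.values[0].ravel(), grid.values[1].ravel())[0, 1]
        assert abs(r - target) < 0.15

    def test_layers_are_spatially_smooth(self):
        grid = generate_landscape(32, 32, 3, smoothness=0.4, correlation=0.0, seed=5)
        layer = grid.values[0]
        lag1 = np.corrcoef(layer[:, :-1].ravel(), layer[:, 1:].ravel())[0, 1]
        assert lag1 > 0.5  # neighboring cells strongly correlated

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_rows=4, n_cols=32, n_layers=2),
            dict(n_rows=32, n_cols=32, n_layers=1),
            dict(n_rows=32, n_cols=32, n_layers=2, correlation=1.5),
            dict(n_rows=32, n_cols=32, n_layers=5, correlation=-0.9),
        ],
    )
    def test_preconditions(self, kwargs):
        with pytest.raises(ArgumentError):
            generate_landscape(**kwargs)


class TestBiomeMasks:
    def test_disjoint_and_bounded(self, landscape):
        a, b = make_biome_masks(landscape, "east_west")
        assert not np.any(a & b)
        assert a.sum() + b.sum() <= (~landscape.nodata_mask).sum()
        assert min(a.sum(), b.sum()) >= 0.10 * (~landscape.nodata_mask).sum()

    def test_custom_rectangles(self, landscape):
        a, b = make_biome_masks(
            landscape, "custom", rectangles=((0, 32, 0, 12), (0, 32, 20, 32))
        )
        assert not np.any(a & b)

    def test_overlapping_rectangles_rejected(self, landscape):
        with pytest.raises(GeometryError):
            make_biome_masks(landscape, "custom", rectangles=((0, 32, 0, 20), (0, 32, 10, 32)))

    def test_degenerate_one_column_geometry(self):
        grid = synthetic.generate_landscape(8, 8, 2, seed=0)
        with pytest.raises(GeometryError):
            make_biome_masks(grid, "east_west", gap=7)


class TestSampleOccurrences:
    @pytest.fixture()
    def truth(self, landscape):
        mask = np.zeros(landscape.shape, dtype=bool)
        mask[:, :16] = True
        _, env = landscape.table(mask)
        cov = np.diag(env.std(axis=0, ddof=1) ** 2)
        return SpeciesTruth("sp", env.mean(axis=0), cov, mask)

    def test_all_records_inside_range_mask(self, truth, landscape):
        occ = sample_occurrences(truth, landscape, 20, seed=3)
        rows = occ.cell_ids // landscape.n_cols
        cols = occ.cell_ids % landscape.n_cols
        assert truth.range_mask[rows, cols].all()
        assert len(occ) == 20

    def test_records_at_cell_centers(self, truth, landscape):
        occ = sample_occurrences(truth, landscape, 5, seed=3)
        assert np.allclose(occ.records, landscape.cell_center(occ.cell_ids))

    def test_seeded_determinism(self, truth, landscape):
        a = sample_occurrences(truth, landscape, 20, seed=9)
        b = sample_occurrences(truth, landscape, 20, seed=9)
        assert np.array_equal(a.cell_ids, b.cell_ids)
        assert np.array_equal(a.records, b.records)

    def test_oversampling_rejected(self, landscape):
        mask = np.zeros(landscape.shape, dtype=bool)
        mask[0, :5] = True
        _, env = landscape.table(mask)
        truth = SpeciesTruth("sp", env.mean(axis=0), np.eye(landscape.n_layers), mask)
        with pytest.raises(SamplingError):
            sample_occurrences(truth, landscape, 6, seed=0)

    def test_selection_frequency_tracks_suitability(self):
        """Across replicate draws, per-cell selection frequency follows true
        suitability (Spearman > 0.7 at n=500 on a 64x64 grid)."""
        grid = generate_landscape(64, 64, 3, smoothness=0.2, correlation=0.3, seed=21)
        mask = np.ones(grid.shape, dtype=bool)
        _, env = grid.table(mask)
        cov = np.diag((0.7 * env.std(axis=0, ddof=1)) ** 2)
        truth = SpeciesTruth("sp", env.mean(axis=0), cov, mask)
        freq = np.zeros(grid.n_cells)
        for s in range(30):
            occ = sample_occurrences(truth, grid, 500, seed=s)
            freq[occ.cell_ids] += 1
        suit = truth.suitability(grid).ravel()
        rho = stats.spearmanr(freq, suit).statistic
        assert rho > 0.7


class TestGenerateScenario:
    def test_conserved_identical_niche_disjoint_ranges(self):
        sc = generate_scenario("conserved_allopatric", 20, seed=1)
        t1, t2 = sc.truths
        assert np.array_equal(t1.niche_centroid, t2.niche_centroid)
        assert np.array_equal(t1.niche_covariance, t2.niche_covariance)
        assert not np.any(t1.range_mask & t2.range_mask)

    def test_sympatric_shared_masks(self):
        sc = generate_scenario("sympatric_shared", 20, seed=1)
        assert np.array_equal(sc.truths[0].range_mask, sc.truths[1].range_mask)
        assert np.array_equal(sc.backgrounds[0], sc.backgrounds[1])

    def test_divergent_mahalanobis_separation(self):
        sc = generate_scenario("divergent_allopatric", 20, seed=1, separation=3.0)
        t1, t2 = sc.truths
        d = t2.niche_centroid - t1.niche_centroid
        maha = np.sqrt(d @ np.linalg.solve(t1.niche_covariance, d))
        assert abs(maha - 3.0) < 1e-9

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ArgumentError):
            generate_scenario("parapatric", 20, seed=1)

    def test_sample_size_floor(self):
        with pytest.raises(ArgumentError):
            generate_scenario("sympatric_shared", 19, seed=1)

    def test_seeded_determinism(self):
        a = generate_scenario("divergent_allopatric", 25, seed=42)
        b = generate_scenario("divergent_allopatric", 25, seed=42)
        assert np.array_equal(a.grid.values, b.grid.values)
        assert np.array_equal(a.occurrences[0].cell_ids, b.occurrences[0].cell_ids)
        assert np.array_equal(a.occurrences[1].cell_ids, b.occurrences[1].cell_ids)


class TestGenerateRemnants:
    def test_full_coverage(self, landscape):
        rm = generate_remnants(landscape, 2, coverage=1.0, seed=0)
        assert rm.mask.all()
        assert rm.shape == (64, 64)

    def test_realized_coverage_fraction(self, landscape):
        rm = generate_remnants(landscape, 2, coverage=0.3, seed=4)
        assert abs(rm.mask.mean() - 0.3) < 0.1

    def test_patchiness_yields_contiguity(self, landscape):
        from scipy import ndimage

        rm = generate_remnants(landscape, 2, coverage=0.3, patchiness=3.0, seed=4)
        _, n = ndimage.label(rm.mask)
        assert n < 0.05 * rm.mask.size  # far fewer patches than cells

    @pytest.mark.parametrize("kwargs", [dict(fine_factor=0, coverage=0.5),
                                        dict(fine_factor=2, coverage=0.0),
                                        dict(fine_factor=2, coverage=1.2)])
    def test_preconditions(self, landscape, kwargs):
        with pytest.raises(ArgumentError):
            generate_remnants(landscape, seed=0, **kwargs)

    def test_seeded_determinism(self, landscape):
        a = generate_remnants(landscape, 2, coverage=0.4, seed=5)
        b = generate_remnants(landscape, 2, coverage=0.4, seed=5)
        assert np.array_equal(a.mask, b.mask)
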