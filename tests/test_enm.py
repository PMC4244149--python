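"""Presence-only models, thresholding, TSS, ensembles, reciprocal projection."""

import numpy as np
import pytest

from conftest import tiny_grid
from nichecmp import enm
from nichecmp.enm import (
    consensus,
    cross_prediction,
    fit_envelope,
    fit_mahalanobis,
    predict_envelope,
    predict_mahalanobis,
    roc_threshold,
    run_ensemble,
    sample_pseudo_absences,
    split_data,
    tss,
    tss_from_confusion,
)
from nichecmp.errors import (
    ArgumentError,
    DegenerateInputError,
    EmptyConsensusError,
    SamplingError,
    SchemaError,
    UndefinedStatisticError,
)
from nichecmp.grids import OccurrenceSet


class TestEnvelope:
    def test_minmax_bounds(self):
        model = fit_envelope(np.array([[1.0], [2.0], [3.0]]))
        assert model.lower[0] == 1.0 and model.upper[0] == 3.0

    def test_percentile_bounds_quantiles(self):
        X = np.arange(101.0).reshape(-1, 1)
        model = fit_envelope(X, percentile=0.25)
        assert model.lower[0] == pytest.approx(25.0, abs=1.0)
        assert model.upper[0] == pytest.approx(75.0, abs=1.0)

    def test_single_presence_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_envelope(np.array([[1.0, 2.0]]))

    def test_suitability_is_fraction_of_layers_inside(self):
        grid = tiny_grid(np.stack([
            np.array([[1.0, 5.0], [2.0, 2.0]]),
            np.array([[1.0, 1.0], [9.0, 1.0]]),
        ]))
        model = fit_envelope(np.array([[0.0, 0.0], [3.0, 3.0]]))
        suit = predict_envelope(model, grid).values
        assert suit[0, 0] == 1.0       # inside both
        assert suit[0, 1] == 0.5       # outside one of two layers
        assert suit[1, 1] == 1.0
        assert suit[1, 0] == 0.5

    def test_training_presences_score_one_under_minmax(self, pc_layers, scenario_divergent):
        occ = scenario_divergent.occurrences[0]
        X = pc_layers.env_at(occ.cell_ids)
        model = fit_envelope(X)
        suit = predict_envelope(model, pc_layers)
        assert np.all(suit.values.ravel()[occ.cell_ids] == 1.0)

    def test_values_on_discrete_ladder(self, pc_layers, scenario_divergent):
        occ = scenario_divergent.occurrences[0]
        model = fit_envelope(pc_layers.env_at(occ.cell_ids))
        suit = predict_envelope(model, pc_layers).values
        k = pc_layers.n_layers
        ladder = np.arange(k + 1) / k
        assert np.all(np.isin(np.round(suit[~np.isnan(suit)] * k), np.arange(k + 1)))
        assert set(np.unique(suit[~np.isnan(suit)])) <= set(ladder)

    def test_layer_mismatch(self):
        grid = tiny_grid(np.zeros((3, 4, 4)))
        model = fit_envelope(np.zeros((3, 2)))
        with pytest.raises(SchemaError):
            predict_envelope(model, grid)


class TestMahalanobis:
    def test_identity_covariance_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 3))
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X.T))).T
        model = fit_mahalanobis(X)
        assert np.allclose(model.covariance, np.eye(3), atol=1e-9)

    def test_suitability_one_at_centroid(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 2))
        model = fit_mahalanobis(X)
        grid = tiny_grid(np.tile(model.centroid.reshape(2, 1, 1), (1, 2, 2)))
        suit = predict_mahalanobis(model, grid)
        assert np.allclose(suit.values, 1.0)

    def test_closed_form_chi2_two_layers(self):
        """With identity covariance and k=2, suitability at unit distance is
        the chi-square(2) survival value exp(-1/2)."""
        model = enm.MahalanobisModel(["a", "b"], np.zeros(2), np.eye(2), False)
        grid = tiny_grid(np.array([1.0, 0.0]).reshape(2, 1, 1))
        suit = predict_mahalanobis(model, grid)
        assert suit.values[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_monotone_decreasing_along_ray(self):
        model = enm.MahalanobisModel(["a", "b"], np.zeros(2), np.eye(2), False)
        ts = np.linspace(0, 3, 7)
        vals = np.stack([ts * 0.6, ts * 0.8])  # ray from the centroid
        suit = predict_mahalanobis(model, tiny_grid(vals.reshape(2, 1, 7))).values.ravel()
        assert np.all(np.diff(suit) < 0)

    def test_affine_invariance(self):
        """Mahalanobis suitability is unchanged by an invertible affine map
        applied consistently to training and prediction data."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        grid_vals = rng.normal(size=(3, 5, 5))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        s1 = predict_mahalanobis(fit_mahalanobis(X), tiny_grid(grid_vals)).values
        Xa = X @ A.T + b
        grid_a = (grid_vals.reshape(3, -1).T @ A.T + b).T.reshape(3, 5, 5)
        s2 = predict_mahalanobis(fit_mahalanobis(Xa), tiny_grid(grid_a)).values
        assert np.allclose(s1, s2, atol=1e-6)

    def test_regularization_engaged_and_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 5))  # fewer presences than layers
        model = fit_mahalanobis(X)
        assert model.regularized
        assert np.all(np.linalg.eigvalsh(model.covariance) > 0)

    def test_constant_layer_rejected(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(DegenerateInputError):
            fit_mahalanobis(X)


class TestSplitsAndPseudoAbsences:
    @pytest.fixture()
    def occ30(self, scenario_divergent):
        cells = scenario_divergent.occurrences[0].cell_ids[:30]
        return OccurrenceSet("sp", scenario_divergent.grid.cell_center(cells), cells)

    def test_seventy_thirty_sizes(self, occ30):
        splits = split_data(occ30, seed=0)
        assert len(splits) == 10
        for train, test in splits:
            assert train.size == 21 and test.size == 9
            assert np.intersect1d(train, test).size == 0
            assert np.array_equal(np.sort(np.concatenate([train, test])),
                                  np.sort(occ30.cell_ids))

    def test_reproducible_partitions(self, occ30):
        a = split_data(occ30, seed=3)
        b = split_data(occ30, seed=3)
        assert all(np.array_equal(x[0], y[0]) for x, y in zip(a, b))

    def test_too_few_occurrences(self, scenario_divergent):
        cells = scenario_divergent.occurrences[0].cell_ids[:5]
        occ = OccurrenceSet("sp", scenario_divergent.grid.cell_center(cells), cells)
        with pytest.raises(ArgumentError):
            split_data(occ)

    def test_pseudo_absences_respect_exclusion(self, scenario_divergent):
        sc = scenario_divergent
        occ = sc.occurrences[0]
        pa = sample_pseudo_absences(sc.grid, sc.backgrounds[0], occ.cell_ids, 25, seed=1)
        assert pa.size == 25
        assert np.intersect1d(pa, occ.cell_ids).size == 0
        assert np.unique(pa).size == 25

    def test_insufficient_eligible_cells(self, scenario_divergent):
        sc = scenario_divergent
        tiny_mask = np.zeros(sc.grid.shape, dtype=bool)
        tiny_mask[0, :3] = True
        with pytest.raises(SamplingError):
            sample_pseudo_absences(sc.grid, tiny_mask, np.array([]), 10, seed=0)


class TestRocThreshold:
    def test_separable_scores_pick_smallest_perfect_cut(self):
        assert roc_threshold([0.9, 0.8], [0.1, 0.2]) == pytest.approx(0.8)

    def test_single_presence_above_absences(self):
        assert roc_threshold([0.7], [0.1, 0.3, 0.5]) == pytest.approx(0.7)

    def test_matches_exhaustive_oracle(self):
        """Vectorized selection equals a brute-force scan of all candidate
        thresholds with the same tie-breaks, on 200 random score sets."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            pres = rng.random(rng.integers(1, 20))
            absn = rng.random(rng.integers(1, 20))
            best = None
            for t in np.unique(np.concatenate([pres, absn])):
                sens = np.mean(pres >= t)
                spec = np.mean(absn < t)
                key = (abs(sens - spec), -(sens + spec), t)
                if best is None or key < best[0]:
                    best = (key, t)
            assert roc_threshold(pres, absn) == pytest.approx(best[1])

    def test_empty_scores_rejected(self):
        with pytest.raises(ArgumentError):
            roc_threshold([], [0.1])


class TestTss:
    def test_arithmetic(self):
        assert tss(1.0, 1.0) == pytest.approx(1.0)
        assert tss(0.5, 0.5) == pytest.approx(0.0)
        assert tss_from_confusion(45, 5, 30, 10) == pytest.approx(0.65)

    def test_empty_margin_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            tss_from_confusion(0, 0, 5, 5)


class TestEnsembleAndConsensus:
    def test_replicate_bookkeeping(self, scenario_divergent, pc_layers):
        sc = scenario_divergent
        maps, evals = run_ensemble(sc.occurrences[0], pc_layers, sc.backgrounds[0], seed=2)
        assert len(maps) == 20 and len(evals) == 20
        assert {e.algorithm for e in evals} == {"envelope", "mahalanobis"}
        for e in evals:
            assert e.tss == pytest.approx(e.sensitivity + e.specificity - 1.0, abs=1e-12)
            assert -1.0 <= e.tss <= 1.0

    def test_sharply_separable_species_scores_high_tss(self):
        """A species confined to a tight environmental pocket is recovered
        with excellent skill (mean TSS >= 0.9)."""
        from nichecmp import envspace, synthetic

        sc = synthetic.generate_scenario("divergent_allopatric", 80, seed=13,
                                         n_rows=96, n_cols=96, n_layers=3,
                                         niche_sd_factor=0.08)
        model = envspace.fit_pca(sc.grid)
        pc = envspace.project_grid(sc.grid, model, envspace.select_components(model))
        _, evals = run_ensemble(sc.occurrences[0], pc, sc.backgrounds[0], seed=13)
        assert np.mean([e.tss for e in evals]) >= 0.9

    def test_label_permutation_destroys_skill(self, scenario_divergent, pc_layers):
        """Permuting presence/pseudo-absence labels leaves no skill: mean TSS
        within 0.15 of zero."""
        sc = scenario_divergent
        maps, evals = run_ensemble(sc.occurrences[0], pc_layers, sc.backgrounds[0], seed=4)
        rng = np.random.default_rng(4)
        null_tss = []
        for e in evals:
            suit_cells = np.concatenate([e.test_cells, e.pseudo_absence_cells])
            # recover the replicate's suitability scores from its stored cells
            scores = np.concatenate([
                np.full(e.test_cells.size, np.nan), np.full(e.pseudo_absence_cells.size, np.nan)
            ])
            # rebuild scores by re-fitting the same algorithm on the same train cells
            algo = enm.ALGORITHMS[e.algorithm]
            suit = algo.predict(algo.fit(pc_layers.env_at(e.train_cells),
                                         list(pc_layers.layer_names)), pc_layers)
            scores = suit.scores_at(suit_cells)
            perm = rng.permutation(scores.size)
            pres = scores[perm[: e.test_cells.size]]
            absn = scores[perm[e.test_cells.size:]]
            t = roc_threshold(pres, absn)
            null_tss.append(tss(np.mean(pres >= t), np.mean(absn < t)))
        assert abs(np.mean(null_tss)) <= 0.15

    def test_consensus_fraction_and_cutoff(self):
        m1 = np.array([[True, False]]); m2 = np.array([[True, True]])
        cons = consensus([m1, m2], [0.5, 0.6], cutoff=0.4)
        assert cons.n_accepted == 2
        assert np.allclose(cons.fraction, [[1.0, 0.5]])

    def test_consensus_all_identical(self):
        m = np.array([[True, False], [False, True]])
        cons = consensus([m, m.copy()], [0.5, 0.5], cutoff=0.4)
        assert np.array_equal(cons.fraction, m.astype(float))

    def test_empty_consensus_is_explicit_error(self):
        with pytest.raises(EmptyConsensusError):
            consensus([np.ones((2, 2), dtype=bool)], [0.4], cutoff=0.4)


class TestReciprocalProjection:
    def test_self_projection_beats_cross(self, scenario_divergent, pc_layers):
        sc = scenario_divergent
        maps, evals = run_ensemble(sc.occurrences[0], pc_layers, sc.backgrounds[0], seed=6)
        cons = consensus(maps, [e.tss for e in evals], cutoff=0.4)
        self_frac = cross_prediction(cons, sc.occurrences[0])
        cross_frac = cross_prediction(cons, sc.occurrences[1])
        assert self_frac >= cross_frac

    def test_conserved_niche_cross_predicts(self):
        """With an identical niche in both biomes, the sister species'
        occurrences fall largely inside the projected consensus."""
        from nichecmp import envspace, reciprocal_projection, synthetic

        fracs = []
        for s in range(5):
            sc = synthetic.generate_scenario("conserved_allopatric", 50, seed=100 + s)
            model = envspace.fit_pca(sc.grid)
            pc = envspace.project_grid(sc.grid, model, envspace.select_components(model))
            fracs.append(reciprocal_projection(sc.occurrences[0], sc.occurrences[1],
                                               pc, sc.backgrounds[0], seed=s))
        assert np.mean(fracs) >= 0.8
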