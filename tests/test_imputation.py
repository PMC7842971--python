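import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.neighbors import NearestNeighbors

import forestknn as fk

from conftest import toy_raster


def brute_force_proximity(model, X_targets):
    """Triple loop over (target, reference, tree) from the leaf matrices."""
    leaves_t = model.apply_forests(np.asarray(X_targets, dtype=float))
    leaves_r = model.ref_leaf_nodes
    n_t, T = leaves_t.shape
    n_r = leaves_r.shape[0]
    prox = np.zeros((n_t, n_r))
    for t in range(n_t):
        for r in range(n_r):
            same = 0
            for tree in range(T):
                if leaves_t[t, tree] == leaves_r[r, tree]:
                    same += 1
            prox[t, r] = same / T
    return prox


class TestRfProximity:
    def test_matches_exhaustive_count_oracle(self, toy_model):
        rng = np.random.default_rng(1)
        Xt = pd.DataFrame(
            rng.normal(size=(10, 3)), columns=toy_model.predictor_names
        )
        fast = fk.rf_proximity(toy_model, Xt)
        slow = brute_force_proximity(toy_model, Xt.to_numpy())
        np.testing.assert_allclose(fast, slow)
        assert fast.min() >= 0.0 and fast.max() <= 1.0

    def test_reference_has_unit_proximity_to_itself(self, toy_model):
        prox = fk.rf_proximity(toy_model, toy_model.X_ref)
        np.testing.assert_allclose(np.diag(prox), 1.0)

    def test_one_tree_two_leaves(self):
        # single tree, references in different leaves -> proximities 1 and 0
        X = pd.DataFrame({"a": [0.0, 0.0, 10.0, 10.0]})
        Y = pd.DataFrame({"y": [0.0, 0.0, 5.0, 5.0]})
        m = fk.fit_knn(X, Y, k=1, ntree=1, mtry=1, seed=0)
        prox = fk.rf_proximity(m, pd.DataFrame({"a": [0.0]}))
        by_leaf = {0: prox[0, 0], 2: prox[0, 2]}
        assert by_leaf[0] == 1.0 and by_leaf[2] == 0.0

    def test_column_mismatch_error_lists_difference(self, toy_model):
        bad = pd.DataFrame(np.zeros((2, 3)), columns=["a", "b", "zz"])
        with pytest.raises(ValueError, match="zz"):
            fk.rf_proximity(toy_model, bad)


class TestImpute:
    def test_k1_copies_nearest_reference_vector(self, toy_model):
        res = fk.impute(toy_model, toy_model.X_ref)
        np.testing.assert_array_equal(res.neighbor_ids[:, 0], np.arange(toy_model.n_ref))
        np.testing.assert_allclose(res.predictions.to_numpy(), toy_model.Y_ref.to_numpy())

    def test_k2_equal_proximity_mean(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 50.0]})
        Y = pd.DataFrame({"y": [10.0, 20.0, 99.0]})
        m = fk.fit_knn(X, Y, k=2, ntree=7, mtry=1, aggregation="mean", seed=0)
        # target in the low leaf: refs 0 and 1 share every leaf (equal proximity)
        res = fk.impute(m, pd.DataFrame({"a": [0.0]}))
        assert res.predictions["y"].iloc[0] == pytest.approx(15.0)

    def test_weighted_mean_hand_oracle(self, monkeypatch):
        m = fk.fit_knn(
            pd.DataFrame({"a": [0.0, 1.0, 2.0]}),
            pd.DataFrame({"y": [8.0, 4.0, 0.0]}),
            k=3, ntree=2, mtry=1, aggregation="distance_weighted_mean", seed=0,
        )
        monkeypatch.setattr(
            fk.imputation, "_neighbor_order",
            lambda model, X: (np.array([[0, 1, 2]]), np.array([[0.5, 0.25, 0.25]])),
        )
        res = fk.impute(m, pd.DataFrame({"a": [0.0]}))
        # (0.5*8 + 0.25*4 + 0.25*0) / 1.0 = 5.0
        assert res.predictions["y"].iloc[0] == pytest.approx(5.0)

    def test_proximity_ties_break_to_lowest_reference_id(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 9.0]})
        Y = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        m = fk.fit_knn(X, Y, k=1, ntree=5, mtry=1, seed=0)
        res = fk.impute(m, pd.DataFrame({"a": [0.05]}))
        assert res.neighbor_ids[0, 0] == 0  # refs 0 and 1 tie; lowest wins

    def test_euclidean_k1_matches_brute_force_nn(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        Y = pd.DataFrame({"y": rng.normal(size=40)})
        m = fk.fit_knn(X, Y, k=1, method="euclidean", seed=0)
        Xt = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        res = fk.impute(m, Xt)
        nn = NearestNeighbors(n_neighbors=1).fit(X.to_numpy())
        _, idx = nn.kneighbors(Xt.to_numpy())
        np.testing.assert_array_equal(res.neighbor_ids[:, 0], idx[:, 0])
        np.testing.assert_allclose(
            res.predictions["y"].to_numpy(), Y.to_numpy()[idx[:, 0], 0]
        )

    def test_mahalanobis_method_runs_and_differs_from_euclidean(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 2))
        X = pd.DataFrame({"a": base[:, 0], "b": base[:, 0] * 5 + base[:, 1] * 0.1})
        Y = pd.DataFrame({"y": rng.normal(size=30)})
        me = fk.fit_knn(X, Y, k=1, method="euclidean")
        mm = fk.fit_knn(X, Y, k=1, method="mahalanobis")
        Xt = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        ids_e = fk.impute(me, Xt).neighbor_ids[:, 0]
        ids_m = fk.impute(mm, Xt).neighbor_ids[:, 0]
        assert not np.array_equal(ids_e, ids_m)

    def test_invalid_configurations_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        Y = pd.DataFrame({"y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="k="):
            fk.fit_knn(X, Y, k=3)
        with pytest.raises(ValueError, match="mtry"):
            fk.fit_knn(X, Y, k=1, mtry=5)
        with pytest.raises(ValueError, match="method"):
            fk.fit_knn(X, Y, k=1, method="cosine")


class TestTrainNN:
    def test_paper_style_configuration_recorded(self, toy_model):
        assert (toy_model.k, toy_model.ntree, toy_model.mtry) == (1, 8, 2)
        m = fk.fit_knn(toy_model.X_ref, toy_model.Y_ref, k=1, ntree=200, mtry=3, seed=0)
        assert m.ntree == 200 and m.mtry == 3 and m.n_trees_total == 2 * 200

    def test_duplicated_test_row_imputes_training_response(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        Y = pd.DataFrame({"y1": rng.normal(size=20), "y2": rng.normal(size=20)})
        m = fk.fit_knn(X, Y, k=1, ntree=50, mtry=2, seed=1)
        res = fk.impute(m, X.iloc[[7]])
        assert res.neighbor_ids[0, 0] == 7
        np.testing.assert_allclose(res.predictions.iloc[0], Y.iloc[7])

    def test_heldout_predictions_match_leaf_matrix_recomputation(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        Y = pd.DataFrame({
            "y1": X["a"] * 2 + rng.normal(0, 0.1, 30),
            "y2": X["b"] - X["a"] + rng.normal(0, 0.1, 30),
        })
        folds = fk.partition(np.ones(30, dtype=int), kfold=3, seed=0)
        cv = fk.train_nn(X, Y, k=1, folds=folds, ntree=5, mtry=2, seed=9)
        # brute-force recomputation for each fold from the stored leaf matrix
        recomputed = []
        for f in sorted(cv.fold_models):
            model = cv.fold_models[f]
            test = folds.fold == f
            prox = brute_force_proximity(model, X.loc[test].to_numpy())
            nearest = np.argmax(prox, axis=1)  # argmax takes lowest index on ties
            recomputed.append(model.Y_ref.to_numpy()[nearest])
        np.testing.assert_allclose(cv.predicted.to_numpy(), np.vstack(recomputed))

    def test_rows_with_missing_values_dropped(self):
        X = pd.DataFrame({"a": [0.0, np.nan, 2.0, 3.0, 4.0, 5.0]})
        Y = pd.DataFrame({"y": [0.0, 1.0, 2.0, 3.0, np.nan, 5.0]})
        folds = fk.partition(np.ones(6, dtype=int), kfold=2, seed=0)
        cv = fk.train_nn(X, Y, k=1, folds=folds, ntree=3, mtry=1, seed=0)
        assert len(cv.observed) == 4

    def test_holdout_scheme(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        Y = pd.DataFrame({"y": X["a"] * 3})
        labels = np.repeat([1, 2], 10)
        folds = fk.partition(labels, scheme="holdout", train_fraction=0.7, seed=1)
        cv = fk.train_nn(X, Y, k=1, folds=folds, ntree=10, mtry=1, seed=0)
        assert len(cv.observed) == (folds.fold == 1).sum()


@pytest.fixture(scope="module")
def raster_setup(toy_model):
    rng = np.random.default_rng(0)
    p = len(toy_model.predictor_names)
    vals = rng.normal(size=(p, 12, 12))
    # plant reference 4's predictor vector at cell (2, 3)
    vals[:, 2, 3] = toy_model.X_ref.iloc[4].to_numpy()
    vals[:, 5, 5] = np.nan  # a NoData predictor cell
    raster = toy_raster(vals, band_names=toy_model.predictor_names)
    return toy_model, raster


class TestPredictTargets:

    def test_reference_cell_imputes_reference_row(self, raster_setup):
        model, raster = raster_setup
        out = fk.predict_targets(model, raster, chunk_rows=5)
        assert out.band("nn_id")[2, 3] == 4
        for resp in model.response_names:
            assert out.band(resp)[2, 3] == pytest.approx(model.Y_ref[resp].iloc[4])

    def test_chunking_equivalence_bit_identical(self, raster_setup):
        model, raster = raster_setup
        whole = fk.predict_targets(model, raster, chunk_rows=12)
        row_by_row = fk.predict_targets(model, raster, chunk_rows=1)
        clamped = fk.predict_targets(model, raster, chunk_rows=999)
        np.testing.assert_array_equal(whole.values, row_by_row.values)
        np.testing.assert_array_equal(whole.values, clamped.values)

    def test_tile_then_mosaic_equals_whole(self, raster_setup):
        model, raster = raster_setup
        whole = fk.predict_targets(model, raster, chunk_rows=4)
        tiles = [fk.predict_targets(model, t, chunk_rows=4) for t in fk.tile(raster, 2, 2)]
        np.testing.assert_array_equal(fk.mosaic(tiles).values, whole.values)

    def test_nodata_predictor_masks_all_outputs(self, raster_setup):
        model, raster = raster_setup
        out = fk.predict_targets(model, raster, chunk_rows=6)
        assert np.isnan(out.values[:, 5, 5]).all()

    def test_k1_closure_over_whole_raster(self, raster_setup):
        model, raster = raster_setup
        out = fk.predict_targets(model, raster, chunk_rows=7)
        ids = out.band("nn_id")
        ok = np.isfinite(ids)
        Y = model.Y_ref.to_numpy()
        for b, resp in enumerate(model.response_names):
            np.testing.assert_allclose(
                out.band(resp)[ok], Y[ids[ok].astype(int), b]
            )

    def test_band_mismatch_error(self, toy_model):
        raster = toy_raster(np.zeros((2, 4, 4)), band_names=["a", "nope"])
        with pytest.raises(ValueError, match="mismatch"):
            fk.predict_targets(toy_model, raster)


class TestAccuracy:
    def test_perfect_prediction(self):
        rep = fk.accuracy([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (rep.r2, rep.rmse, rep.bias) == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        rep = fk.accuracy(obs, np.full(4, obs.mean()))
        assert rep.r2 == pytest.approx(0.0)

    def test_hand_computed_statistics(self):
        rep = fk.accuracy([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert rep.ssr == pytest.approx(2.0)
        assert rep.sst == pytest.approx(2.0)
        assert rep.r2 == pytest.approx(0.0)
        assert rep.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert rep.bias == pytest.approx(0.0)
        assert rep.rmse_pct == pytest.approx(100.0 * np.sqrt(2.0 / 3.0) / 2.0)

    def test_zero_mean_observed_warns_and_relative_undefined(self):
        with pytest.warns(UserWarning, match="relative"):
            rep = fk.accuracy([-1.0, 1.0], [0.0, 0.0])
        assert np.isnan(rep.rmse_pct) and np.isnan(rep.bias_pct)

    def test_missing_pairs_dropped(self):
        rep = fk.accuracy([1.0, np.nan, 3.0, 4.0], [1.5, 2.0, np.nan, 4.5])
        assert rep.n == 2

    @given(
        st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=2, max_size=30,
        ).filter(lambda pairs: np.var([p[0] for p in pairs]) > 1e-6)
    )
    @settings(deadline=None, max_examples=60)
    def test_rmse_bounds_bias_and_r2_at_most_one(self, pairs):
        obs = [p[0] for p in pairs]
        pred = [p[1] for p in pairs]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = fk.accuracy(obs, pred)
        assert rep.rmse >= abs(rep.bias) - 1e-12
        assert rep.r2 <= 1.0 + 1e-12


@pytest.fixture(scope="module")
def informative_model():
    rng = np.random.default_rng(0)
    n = 60
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("ABCDE"))
    Y = pd.DataFrame({"y": X["A"].to_numpy().copy()})  # response = predictor A
    return fk.fit_knn(X, Y, k=1, ntree=60, mtry=2, seed=0)


class TestVarImp:

    def test_zscores_have_zero_mean_unit_variance(self, informative_model):
        rep = fk.var_imp(informative_model, scaled=True, seed=0)
        z = rep.scaled["y"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)
        assert rep.scaled.loc["A", "y"] > 0  # informative predictor above mean

    def test_informative_predictor_dominates_across_seeds(self):
        rng = np.random.default_rng(10)
        wins = 0
        n_reps = 20
        for rep_i in range(n_reps):
            n = 40
            X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("ABCDE"))
            Y = pd.DataFrame({"y": X["A"].to_numpy().copy()})
            m = fk.fit_knn(X, Y, k=1, ntree=200, mtry=2, seed=rep_i)
            imp = fk.var_imp(m, scaled=False, seed=rep_i)
            if imp.raw["y"].idxmax() == "A":
                wins += 1
        assert wins >= 19  # ~95% rank dominance

    def test_equal_raw_importances_zscore_to_zero(self):
        # constant response: no split helps, every raw importance is equal
        # (zero), and the degenerate z-score is reported as 0 for all
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        Y = pd.DataFrame({"y": np.full(25, 7.0)})
        m = fk.fit_knn(X, Y, k=1, ntree=20, mtry=1, seed=0)
        rep = fk.var_imp(m, scaled=True, seed=0)
        assert (rep.raw["y"] == rep.raw["y"].iloc[0]).all()
        assert (rep.scaled["y"] == 0.0).all()

    def test_single_predictor_scaled_warns(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        Y = pd.DataFrame({"y": np.arange(20.0)})
        m = fk.fit_knn(X, Y, k=1, ntree=10, mtry=1, seed=0)
        with pytest.warns(UserWarning, match="single predictor"):
            rep = fk.var_imp(m, scaled=True, seed=0)
        assert (rep.scaled["y"] == 0).all()

    def test_requires_random_forest_method(self):
        X = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        Y = pd.DataFrame({"y": [0.0, 1.0]})
        m = fk.fit_knn(X, Y, k=1, method="euclidean")
        with pytest.raises(ValueError, match="random_forest"):
            fk.var_imp(m)


class TestScatterReport:
    def test_perfect_predictions_plot_written(self, tmp_path):
        rep = fk.accuracy(np.arange(10.0), np.arange(10.0), name="p95")
        path = fk.scatter_report(rep, tmp_path / "scatter.png")
        import os
        assert os.path.getsize(path) > 0

    def test_crossval_result_multi_panel(self, tmp_path, toy_model):
        folds = fk.partition(np.ones(toy_model.n_ref, dtype=int), kfold=5, seed=0)
        cv = fk.train_nn(toy_model.X_ref, toy_model.Y_ref, k=1, folds=folds,
                         ntree=8, mtry=2, seed=0)
        path = fk.scatter_report(cv, tmp_path / "cv.png")
        import os
        assert os.path.getsize(path) > 0

    def test_constant_predictions_still_plot(self, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = fk.accuracy(np.arange(8.0), np.full(8, 3.5), name="flat")
        path = fk.scatter_report(rep, tmp_path / "flat.png")
        import os
        assert os.path.getsize(path) > 0
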