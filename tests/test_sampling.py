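import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

import forestknn as fk
from forestknn.sampling import largest_remainder_quotas

from conftest import toy_raster


class TestKmeansStratify:
    def test_value_separated_populations_recovered(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.0, 1.0, size=(12, 12))
        high = rng.random((12, 12)) < 0.5  # spatially mixed
        vals[high] += 100.0
        strata, centers = fk.kmeans_stratify(toy_raster(vals), 2, seed=0)
        labels = strata.values[0]
        # the two populations must map one-to-one onto the two strata
        assert len(np.unique(labels[high])) == 1
        assert len(np.unique(labels[~high])) == 1
        assert labels[high][0] != labels[~high][0]

    def test_two_band_five_strata_labels(self):
        rng = np.random.default_rng(1)
        r = toy_raster(rng.normal(size=(2, 20, 20)), band_names=["p95", "cover"])
        strata, centers = fk.kmeans_stratify(r, 5, seed=3)
        labels = strata.values[0]
        assert set(np.unique(labels)) == {1, 2, 3, 4, 5}
        assert list(centers.index) == [1, 2, 3, 4, 5]
        assert list(centers.columns) == ["p95", "cover"]

    def test_nodata_cells_stay_nodata(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        vals[0, :] = np.nan
        strata, _ = fk.kmeans_stratify(toy_raster(vals), 2, seed=0)
        assert np.isnan(strata.values[0, 0, :]).all()
        assert np.isfinite(strata.values[0, 1:, :]).all()

    def test_lloyd_fixed_point(self):
        # at convergence every cell must be assigned to the nearest stratum
        # centroid in standardized space (one plain Lloyd iteration is a no-op)
        rng = np.random.default_rng(5)
        r = toy_raster(rng.normal(size=(2, 10, 10)), band_names=["a", "b"])
        strata, _ = fk.kmeans_stratify(r, 3, seed=2)
        X = r.values.reshape(2, -1).T
        Xs = (X - X.mean(0)) / X.std(0)
        labels = strata.values[0].ravel().astype(int)
        means = np.stack([Xs[labels == s].mean(0) for s in (1, 2, 3)])
        d = ((Xs[:, None, :] - means[None]) ** 2).sum(-1)
        np.testing.assert_array_equal(np.argmin(d, axis=1) + 1, labels)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        r = toy_raster(rng.normal(size=(15, 15)))
        a, _ = fk.kmeans_stratify(r, 4, seed=11)
        b, _ = fk.kmeans_stratify(r, 4, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_many_strata_rejected(self):
        with pytest.raises(ValueError):
            fk.kmeans_stratify(toy_raster(np.ones((2, 2))), 10, seed=0)


class TestQuotas:
    def test_sixty_forty_split(self):
        # largest-remainder arithmetic by hand: 10 * .6 = 6, 10 * .4 = 4
        np.testing.assert_array_equal(largest_remainder_quotas([60, 40], 10), [6, 4])

    def test_remainder_assignment(self):
        # shares 4.6 / 3.2 / 2.2 -> floors 4/3/2 + one seat to largest remainder
        np.testing.assert_array_equal(largest_remainder_quotas([46, 32, 22], 10), [5, 3, 2])

    @given(
        counts=st.lists(st.integers(1, 500), min_size=1, max_size=8),
        n=st.integers(1, 300),
    )
    @settings(deadline=None, max_examples=100)
    def test_quotas_sum_and_near_proportionality(self, counts, n):
        q = largest_remainder_quotas(np.asarray(counts), n)
        assert q.sum() == n
        exact = n * np.asarray(counts) / sum(counts)
        assert np.all(np.abs(q - exact) < 1.0)


class TestDrawSample:
    def test_exhaustive_sample_when_n_equals_cells(self):
        labels = np.ones((6, 6))
        strata = toy_raster(labels)
        pts = fk.draw_sample(strata, fk.SampleDesign(n=36, n_strata=1, min_dist=0.0, seed=0))
        assert len(pts) == 36
        assert len(set(zip(pts.data["row"], pts.data["col"]))) == 36

    def test_min_distance_enforced_pairwise(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 4, size=(40, 40)).astype(float)
        strata = toy_raster(labels)  # 30 m cells
        pts = fk.draw_sample(strata, fk.SampleDesign(n=60, n_strata=3, min_dist=75.0, seed=2))
        xy = pts.data[["x", "y"]].to_numpy()
        assert pdist(xy).min() >= 75.0

    def test_quota_proportional_to_stratum_area(self):
        labels = np.ones((10, 10))
        labels[:, :4] = 2.0  # 40% stratum 2, 60% stratum 1
        pts = fk.draw_sample(toy_raster(labels), fk.SampleDesign(n=10, n_strata=2, seed=1))
        counts = pts.data["stratum"].value_counts()
        assert counts[1] == 6 and counts[2] == 4

    def test_points_on_cell_centers_and_labels_match_raster(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(1, 3, size=(8, 8)).astype(float)
        strata = toy_raster(labels)
        pts = fk.draw_sample(strata, fk.SampleDesign(n=20, n_strata=2, seed=5))
        x, y = strata.spec.cell_center(pts.data["row"], pts.data["col"])
        np.testing.assert_allclose(pts.data["x"], x)
        np.testing.assert_allclose(pts.data["y"], y)
        np.testing.assert_array_equal(
            labels[pts.data["row"], pts.data["col"]], pts.data["stratum"]
        )

    def test_unreachable_quota_warns_and_falls_short(self):
        labels = np.ones((4, 4))
        strata = toy_raster(labels)  # 4x4 at 30 m: max spread ~127 m
        with pytest.warns(UserWarning, match="stratum"):
            pts = fk.draw_sample(
                strata, fk.SampleDesign(n=16, n_strata=1, min_dist=100.0, seed=0)
            )
        assert 0 < len(pts) < 16
        xy = pts.data[["x", "y"]].to_numpy()
        if len(pts) > 1:
            assert pdist(xy).min() >= 100.0

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(9)
        strata = toy_raster(rng.integers(1, 4, size=(20, 20)).astype(float))
        design = fk.SampleDesign(n=40, n_strata=3, min_dist=60.0, seed=123)
        a = fk.draw_sample(strata, design)
        b = fk.draw_sample(strata, design)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestGetSampleValues:
    def test_reads_containing_cell_value(self):
        vals = np.zeros((3, 3))
        vals[1, 2] = 7.0
        r = toy_raster(vals)
        x, y = r.spec.cell_center(1, 2)
        pts = fk.SamplePoints(pd.DataFrame({"x": [float(x)], "y": [float(y)]}), crs_id=r.crs_id)
        out = fk.get_sample_values(r, pts)
        assert out.data["b1"].iloc[0] == 7.0

    def test_nodata_cell_recorded_missing_point_retained(self):
        vals = np.full((3, 3), np.nan)
        r = toy_raster(vals)
        x, y = r.spec.cell_center(0, 0)
        pts = fk.SamplePoints(pd.DataFrame({"x": [float(x)], "y": [float(y)]}))
        out = fk.get_sample_values(r, pts)
        assert len(out) == 1 and np.isnan(out.data["b1"].iloc[0])

    def test_out_of_extent_warns(self):
        r = toy_raster(np.zeros((3, 3)))
        pts = fk.SamplePoints(pd.DataFrame({"x": [-1000.0], "y": [1e7]}))
        with pytest.warns(UserWarning, match="outside"):
            out = fk.get_sample_values(r, pts)
        assert np.isnan(out.data["b1"].iloc[0])

    def test_ramp_extraction_matches_geotransform_arithmetic(self):
        ncol = 7
        vals = np.arange(49, dtype=float).reshape(7, 7)  # value = row*ncol + col
        r = toy_raster(vals)
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 7, 20)
        cols = rng.integers(0, 7, 20)
        x, y = r.spec.cell_center(rows, cols)
        pts = fk.SamplePoints(pd.DataFrame({"x": x, "y": y}))
        out = fk.get_sample_values(r, pts)
        np.testing.assert_array_equal(out.data["b1"], rows * ncol + cols)

    def test_crs_mismatch_rejected(self):
        r = toy_raster(np.zeros((2, 2)))
        pts = fk.SamplePoints(pd.DataFrame({"x": [0.0], "y": [0.0]}), crs_id="EPSG:4326")
        with pytest.raises(ValueError, match="CRS"):
            fk.get_sample_values(r, pts)


class TestPartition:
    def test_230_points_five_folds_gives_46_per_fold(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 6, size=230)
        folds = fk.partition(labels, kfold=5, seed=0)
        sizes = np.bincount(folds.fold)[1:]
        np.testing.assert_array_equal(sizes, [46] * 5)
        train, test = folds.train_test(1)
        assert train.sum() == 184 and test.sum() == 46

    def test_within_stratum_fold_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 5, size=97)
        folds = fk.partition(labels, kfold=5, seed=3)
        for s in np.unique(labels):
            sizes = np.bincount(folds.fold[labels == s], minlength=6)[1:]
            assert sizes.max() - sizes.min() <= 1

    def test_two_strata_of_five_with_five_folds(self):
        labels = np.array([1] * 5 + [2] * 5)
        folds = fk.partition(labels, kfold=5, seed=0)
        for f in range(1, 6):
            members = labels[folds.fold == f]
            assert sorted(members) == [1, 2]  # exactly one point per stratum

    def test_holdout_near_one_leaves_one_test_point_per_stratum(self):
        labels = np.array([1] * 8 + [2] * 5 + [3] * 7)
        folds = fk.partition(labels, scheme="holdout", train_fraction=0.99, seed=0)
        for s in (1, 2, 3):
            assert (folds.fold[labels == s] == 1).sum() == 1

    def test_union_of_folds_partitions_points(self):
        labels = np.repeat([1, 2, 3], 10)
        folds = fk.partition(labels, kfold=4, seed=2)
        assert np.all(folds.fold >= 1) and np.all(folds.fold <= 4)
        assert len(folds.fold) == 30

    def test_kfold_exceeding_smallest_stratum_warns(self):
        labels = np.array([1] * 3 + [2] * 20)
        with pytest.warns(UserWarning, match="smallest stratum"):
            fk.partition(labels, kfold=5, seed=0)

    def test_seeded_bit_reproducibility(self):
        labels = np.repeat([1, 2, 3, 4, 5], 46)
        a = fk.partition(labels, kfold=5, seed=42)
        b = fk.partition(labels, kfold=5, seed=42)
        np.testing.assert_array_equal(a.fold, b.fold)
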