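import numpy as np
import pandas as pd
import pytest

import forestknn as fk


def toy_raster(values, band_names=None, cell=30.0, ox=0.0, oy=None, crs="EPSG:32610"):
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[np.newaxis]
    if oy is None:
        oy = values.shape[1] * cell
    names = band_names or [f"b{i+1}" for i in range(values.shape[0])]
    return fk.GridRaster(
        values=values, band_names=names, origin_x=ox, origin_y=oy,
        cell_size_x=cell, cell_size_y=cell, crs_id=crs,
    )


@pytest.fixture
def ramp_raster():
    """5x5 single-band ramp: value = row * ncol + col."""
    vals = np.arange(25, dtype=float).reshape(5, 5)
    return toy_raster(vals)


@pytest.fixture(scope="session")
def toy_model():
    """Small deterministic RF-proximity k-NN model on separable references."""
    rng = np.random.default_rng(7)
    n = 30
    X = pd.DataFrame({
        "a": np.concatenate([rng.normal(0, 1, n // 2), rng.normal(8, 1, n - n // 2)]),
        "b": rng.normal(0, 1, n),
        "c": rng.normal(0, 1, n),
    })
    Y = pd.DataFrame({
        "y1": 3.0 * X["a"] + rng.normal(0, 0.3, n),
        "y2": 10.0 - X["a"] + rng.normal(0, 0.3, n),
    })
    return fk.fit_knn(X, Y, k=1, ntree=8, mtry=2, seed=3)


def run_study(seed, n_rows=100, n_cols=100, noise_sd_frac=0.10, n=230,
              n_strata=5, min_dist=75.0, kfold=5, k=1, ntree=200, mtry=3):
    """Full synthetic study: scene -> strips -> indices -> temporal metrics
    -> stratified sample -> balanced folds -> cross-validated k-NN.

    Returns (scene, reference responses, predictor raster, points, folds, cv).
    """
    scene = fk.make_scene(fk.SceneParams(
        n_rows=n_rows, n_cols=n_cols, seed=seed, noise_sd_frac=noise_sd_frac,
    ))
    ref = fk.make_reference_strips(scene.responses, 3, max(1, n_cols // 6))
    bm = fk.BandMap(bands={r: r for r in ("blue", "green", "red", "nir", "swir1", "swir2")})
    layers = [fk.calc_indices(l, ["NDVI", "TCB", "TCG", "TCW"], bm) for l in scene.series.layers]
    summ = fk.temporal_summary(fk.RasterTimeSeries(layers, list(scene.series.years)))
    predictors = summ.with_values(
        np.concatenate([summ.values, scene.dem.values, scene.slope.values]),
        band_names=summ.band_names + scene.dem.band_names + scene.slope.band_names,
    )
    strata, _ = fk.kmeans_stratify(ref, n_strata, seed=seed)
    pts = fk.draw_sample(strata, fk.SampleDesign(n=n, n_strata=n_strata, min_dist=min_dist, seed=seed))
    pts = fk.get_sample_values(ref, pts)
    pts = fk.get_sample_values(predictors, pts)
    folds = fk.partition(pts.data["stratum"].to_numpy(), kfold=kfold, seed=seed)
    cv = fk.train_nn(
        pts.values_frame(predictors.band_names), pts.values_frame(ref.band_names),
        k=k, folds=folds, ntree=ntree, mtry=mtry, seed=seed,
    )
    return scene, ref, predictors, pts, folds, cv


@pytest.fixture(scope="session")
def study():
    """One full study run shared by the slower end-to-end tests."""
    return run_study(seed=1)
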