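"""Cross-validated random-forest-proximity k-NN imputation.

Trains the k-NN model (k=1, 200 trees per response, 3 split candidates)
on 14 predictors extracted at the sampled cells and reports held-out
accuracy per response, plus which predictors the forests actually used.
"""

import numpy as np

import forestknn as fk

scene = fk.make_scene(fk.SceneParams(seed=4))
ref = fk.make_reference_strips(scene.responses, 3, 16)

band_map = fk.BandMap(bands={r: r for r in ("blue", "green", "red", "nir", "swir1", "swir2")})
layers = [fk.calc_indices(l, ["NDVI", "TCB", "TCG", "TCW"], band_map) for l in scene.series.layers]
metrics = fk.temporal_summary(fk.RasterTimeSeries(layers, list(scene.series.years)))
predictors = metrics.with_values(
    np.concatenate([metrics.values, scene.dem.values, scene.slope.values]),
    band_names=metrics.band_names + ["DEM", "DEM_slope"],
)

strata, _ = fk.kmeans_stratify(ref, 5, seed=4)
points = fk.draw_sample(strata, fk.SampleDesign(n=230, n_strata=5, min_dist=75.0, seed=4))
points = fk.get_sample_values(ref, points)
points = fk.get_sample_values(predictors, points)
folds = fk.partition(points.data["stratum"].to_numpy(), kfold=5, seed=4)

cv = fk.train_nn(
    points.values_frame(predictors.band_names),
    points.values_frame(ref.band_names),
    k=1, folds=folds, ntree=200, mtry=3, seed=4,
)

print("held-out accuracy pooled over the 5 folds:")
print(cv.accuracy_table().round(3).to_string())
print("\nR2 is 1 - SSR/SST; RMSE% and bias% are relative to the observed mean.")

importance = fk.var_imp(cv.final_model, scaled=True, seed=4)
print("\ntop predictors by mean z-scored importance across responses:")
print(importance.mean_scaled.sort_values(ascending=False).head(5).round(2).to_string())
print("(negative z-scores mean below-average importance)")
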