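"""Derive spectral-trend predictors from an annual image time series.

Computes NDVI and Tasseled Cap indices for each yearly composite, then
reduces each index series per pixel to its median, interquartile range and
Theil-Sen slope — the summary metrics used as predictors downstream.
"""

import numpy as np

import forestknn as fk

scene = fk.make_scene(fk.SceneParams(n_rows=60, n_cols=60, seed=2))

band_map = fk.BandMap(
    bands={r: r for r in ("blue", "green", "red", "nir", "swir1", "swir2")},
    sensor="landsat5tm",
)
index_layers = [
    fk.calc_indices(layer, ["NDVI", "TCB", "TCG", "TCW"], band_map)
    for layer in scene.series.layers
]
series = fk.RasterTimeSeries(index_layers, list(scene.series.years))
metrics = fk.temporal_summary(series, metrics=["median", "IQR", "theil_sen"])

print(f"{len(series)} yearly layers x 4 indices -> {metrics.n_bands} metric bands:")
print(" ", ", ".join(metrics.band_names))

# the generator records the true NDVI baseline and trend behind each pixel,
# so the estimated metrics can be compared with what generated the data
r, c = 30, 30
est_median = metrics.band("NDVI_median")[r, c]
est_slope = metrics.band("NDVI_theil_sen")[r, c]
true_median = scene.truth["ndvi_median"].values[0, r, c]
true_slope = scene.truth["ndvi_slope"].values[0, r, c]
print(f"pixel ({r},{c}): NDVI median {est_median:.4f} (true {true_median:.4f}), "
      f"Theil-Sen slope {est_slope:+.5f}/yr (true {true_slope:+.5f}/yr)")
print("the small gaps are the per-year reflectance noise the median and "
      "Theil-Sen estimators are designed to shrug off")
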