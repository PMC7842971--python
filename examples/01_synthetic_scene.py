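"""Generate a synthetic study scene and inspect its pieces.

The scene emulates the inputs of a forest-structure imputation study on a
30 m grid: a 25-year series of six-band reflectance composites, terrain,
a forested mask, and two canopy response rasters (elev_p95 in metres,
cover in percent) tied to the predictors by a known link.
"""

import numpy as np

import forestknn as fk

scene = fk.make_scene(fk.SceneParams(n_rows=80, n_cols=80, seed=1))

print(f"years: {scene.series.years[0]}..{scene.series.years[-1]} "
      f"({len(scene.series)} annual composites)")
print(f"grid: {scene.dem.n_rows} x {scene.dem.n_cols} cells at "
      f"{scene.dem.cell_size_x:.0f} m ({scene.dem.crs_id})")

for name in scene.responses.band_names:
    band = scene.responses.band(name)
    print(f"{name}: min {np.nanmin(band):.1f}  mean {np.nanmean(band):.1f}  "
          f"max {np.nanmax(band):.1f}  (noise sd {scene.truth['noise_sd'][name]:.2f})")

# reference strips emulate discontinuous acquisition blocks: responses are
# only observed inside the strips, the rest of the scene is imputation target
ref = fk.make_reference_strips(scene.responses, n_strips=3, strip_width_cells=13)
n_ref = int(np.isfinite(ref.values[0]).sum())
n_all = int(np.isfinite(scene.responses.values[0]).sum())
print(f"reference cells in strips: {n_ref} of {n_all} observed cells "
      f"({100 * n_ref / n_all:.0f}%)")
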