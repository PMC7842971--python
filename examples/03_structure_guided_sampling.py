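"""Structure-guided sampling: k-means strata, spaced sample, balanced folds.

Reference cells are clustered in response space so the model sample spans
the full range of forest structure; points are drawn proportionally to
cluster area with a 75 m minimum spacing, and cross-validation folds keep
the cluster balance.
"""

import numpy as np
from scipy.spatial.distance import pdist

import forestknn as fk

scene = fk.make_scene(fk.SceneParams(n_rows=100, n_cols=100, seed=3))
ref = fk.make_reference_strips(scene.responses, n_strips=3, strip_width_cells=16)

strata, centers = fk.kmeans_stratify(ref, n_strata=5, seed=3)
print("per-stratum mean responses (original units):")
print(centers.round(1).to_string())

design = fk.SampleDesign(n=230, n_strata=5, min_dist=75.0, seed=3)
points = fk.draw_sample(strata, design)
spacing = pdist(points.data[["x", "y"]].to_numpy()).min()
print(f"\ndrew {len(points)} cell centroids, closest pair {spacing:.1f} m apart "
      f"(constraint: >= {design.min_dist:.0f} m)")
print("points per stratum (proportional to stratum area):")
print(points.data["stratum"].value_counts().sort_index().to_string())

folds = fk.partition(points.data["stratum"].to_numpy(), kfold=5, seed=3)
sizes = np.bincount(folds.fold)[1:]
print(f"\n5-fold split sizes: {sizes.tolist()} "
      f"(training {len(points) - sizes[0]} / testing {sizes[0]} per fold)")
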