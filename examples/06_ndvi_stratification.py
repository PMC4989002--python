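"""NDVI-based stratification for plot placement.

Builds a synthetic land-use raster with a multi-date NDVI stack, averages
the stack per pixel, clusters the mean NDVI into strata with k-means, and
draws disjoint calibration/validation pixel centroids per stratum.
"""

import numpy as np

from savagb import (
    MODEL_LUCAS,
    SimulationConfig,
    generate_landscape,
    mean_ndvi,
    ndvi,
    rescale_255,
    stratify_and_sample,
)

print(f"NDVI for NIR 0.6, Red 0.2: {ndvi(0.6, 0.2):.2f}")

grid, stack = generate_landscape(MODEL_LUCAS, (20, 20), SimulationConfig(seed=1))
composite = mean_ndvi(stack)
print(f"mean-NDVI composite over {stack.shape[0]} dates: "
      f"range {composite.min():.3f} to {composite.max():.3f}")
stretched = rescale_255(composite)
print(f"0-255 stretch: min {stretched.min()}, max {stretched.max()}")

sample = stratify_and_sample(
    composite, k=len(MODEL_LUCAS), n_per_stratum=6, seed=1,
    cell_size=grid.cellsize, validation_fraction=0.5,
)
print()
print(sample.groupby(["stratum", "role"]).size().unstack(fill_value=0))
print("\nEach stratum contributes its own calibration and validation pixel "
      "centroids; the two roles never share a pixel.")
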