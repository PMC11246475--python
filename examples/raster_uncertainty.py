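"""Pixel-wise uncertainty layers from a probability raster.

Builds a spatially correlated synthetic probability raster (per-class
bands plus a nodata stripe), calibrates from a tabular sample, applies the
calibrated classifier pixel-wise, and derives a class-inclusion mask —
the raster products used to map where a class of interest might occur.
"""

import numpy as np

import conformap as cm

# calibration sample (tabular) and a scene to map (raster)
probs_tab, labels_tab = cm.gen_classification_table(
    cm.ClassificationGeneratorSpec(n=4_000, n_classes=5, seed=3)
)
calibration = cm.calibrate_lac(probs_tab, labels_tab, alpha=0.10)

scene, true_labels = cm.gen_probability_raster(
    height=128, width=128, n_classes=5, correlation_length=8.0, seed=3
)

setmask = cm.classify_raster(scene, calibration, alpha=0.10, tile=64)
lengths = setmask.length.data[0]
valid = lengths != 255

print(f"scene: {scene.shape[0]}x{scene.shape[1]} pixels, "
      f"{scene.n_bands} classes, {int((~valid).sum())} nodata pixels")
print("set-length distribution over valid pixels:")
for size in range(int(lengths[valid].max()) + 1):
    frac = float(np.mean(lengths[valid] == size))
    print(f"  length {size}: {frac:.1%}")

confident = cm.class_inclusion_mask(setmask, 0, length="singleton")
possible = cm.class_inclusion_mask(setmask, 0, length="multi")
print(f"\nclass 0: {int((confident.data[0] == 1).sum())} pixels confidently "
      f"(only) class 0; {int((possible.data[0] == 1).sum())} pixels where "
      "class 0 co-occurs with other candidates")

cm.write_geotiff("scratch_setlength.tif", setmask.length)
print("wrote scratch_setlength.tif (8-bit set-length band, nodata=255)")

# Length-1 pixels are confident predictions; longer sets flag boundary and
# mixed pixels where several classes remain plausible at 90% confidence,
# and length 0 marks pixels unlike the calibration data.
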