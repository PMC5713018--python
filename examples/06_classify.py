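"""End-to-end benthic habitat mapping on a four-class mosaic.

simulate (with glint) -> deglint -> invert -> SVM classify, reporting
Jeffries-Matusita separability, overall accuracy and kappa.
"""

import numpy as np

import shallowsea as ss

cfg = ss.four_class_mosaic_config(shape=(36, 36), seed=11, glint_amplitude=0.04)
truth = ss.generate(cfg)

gm = ss.fit_glint_slopes(truth.observed, nir_index=6)
cube = ss.apply_deglint(truth.observed, gm)
res = ss.invert_scene(cube[:6], cfg.geometry, truth.lib, truth.bands.subset(6))

features = np.concatenate([res["abundance"], res["z"][None]])
names = [c.name for c in cfg.classes]
regions = ss.regions_from_class_map(truth.class_map, names, 40, 40, seed=1)

jm = ss.jm_separability(features, regions)
print("pairwise Jeffries-Matusita (2 = fully separable):")
for i in range(len(names)):
    for j in range(i + 1, len(names)):
        print(f"  {names[i]:8s} vs {names[j]:8s}: {jm[i, j]:.3f}")

pred = ss.train_classify(features, regions)
report = ss.confusion_metrics(pred, regions)
print(f"\noverall accuracy: {report.overall_accuracy:.2f}%   "
      f"kappa: {report.kappa:.3f}")
print("confusion matrix (ground-truth percent):")
print(np.round(report.matrix_percent, 2))
print("\nAbundance + depth features separate the four habitat classes almost")
print("perfectly on this synthetic mosaic; misclassifications concentrate at")
print("patch borders where the true cover is mixed.")
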