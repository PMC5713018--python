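"""Remove sunglint streaks from a synthetic coastal scene.

Generates the same scene with and without glint, fits the NIR-excess
regression, applies the correction and reports per-band residuals
against the glint-free truth.
"""

import numpy as np

import shallowsea as ss

base = dict(shape=(40, 40), seed=3, depth_kind="gradient", depth_range=(1.0, 10.0))
clean = ss.generate(ss.SceneConfig(**base))
glinted = ss.generate(ss.SceneConfig(**base, glint_amplitude=0.05))

gm = ss.fit_glint_slopes(glinted.observed, nir_index=6)
corrected = ss.apply_deglint(glinted.observed, gm)

print("fitted per-band slopes vs NIR:", np.round(gm.slopes, 3))
print("ambient NIR baseline: %.2e" % gm.baseline)
for b, name in enumerate(clean.bands.names[:6]):
    before = np.sqrt(np.mean((glinted.observed[b] - clean.observed[b]) ** 2))
    after = np.sqrt(np.mean((corrected[b] - clean.observed[b]) ** 2))
    print(f"  {name:8s} RMSE vs truth: {before:.4f} -> {after:.5f}")
print("\nGlint adds up to ~0.05 reflectance along the streaks; after the")
print("NIR-excess subtraction the visible bands sit within a few 1e-4 of truth.")
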