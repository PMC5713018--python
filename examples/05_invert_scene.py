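"""Retrieve bathymetry, IOPs and benthic abundances for a small scene.

Runs the per-pixel inversion on a noiseless 24x24 depth-gradient scene
and compares the retrievals with the generator's ground truth.
"""

import numpy as np

import shallowsea as ss

cfg = ss.SceneConfig(shape=(24, 24), seed=1, depth_kind="gradient")
truth = ss.generate(cfg)

res = ss.invert_scene(truth.observed[:6], cfg.geometry, truth.lib,
                      truth.bands.subset(6))

rel = (res["z"] - truth.z) / truth.z
print("depth:      rel RMSE %.2f%%  (range %.1f-%.1f m)"
      % (100 * np.sqrt(np.mean(rel ** 2)), truth.z.min(), truth.z.max()))
print("abundances: RMSE %.4f"
      % np.sqrt(np.mean((res["abundance"] - truth.abundance) ** 2)))
for k in ("G", "P", "X"):
    t = getattr(truth, k)
    print(f"{k}:          rel RMSE %.2f%%"
          % (100 * np.sqrt(np.mean(((res[k] - t) / t) ** 2))))
print("flagged pixels:", int((res["flags"] != 0).sum()), "of", truth.z.size)
print("\nDepth and bottom composition are recovered to well under a percent")
print("on noiseless input; IOP errors are larger where the water signal is")
print("masked by a bright bottom.")
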