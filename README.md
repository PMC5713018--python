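# shallowsea

Shallow-water radiative-transfer inversion for coastal benthic mapping.

`shallowsea` retrieves, per pixel of an atmospherically corrected
multispectral image of optically shallow water, the water column's
inherent optical properties, the bathymetry, and the composition of the
seafloor — then maps benthic habitat from those retrievals.  It is aimed
at coastal remote-sensing practitioners working with high-resolution
6–8-band sensors (WorldView-2-class) over clear, shallow littoral zones
such as seagrass meadows, and at anyone who wants a fully synthetic,
ground-truthed test bed for this class of algorithm.

## The model

The sub-surface remote-sensing reflectance of optically shallow water is
a semi-analytical two-stream mixture of a water-column term and a bottom
term attenuated along the two-way path (Beer–Lambert):

```
rrs(λ) = rrs∞(λ) · (1 − exp(−[1/μs' + Duc/μv'] · kd · z))
       + (ρalb(λ)/π) · exp(−[1/μs' + Dub/μv'] · kd · z)
```

where `rrs∞(u) = 0.0512·u·(1 + 4.6659u − 7.8387u² + 5.4571u³)` (times
sun/view factors) is the optically-deep reflectance driven by the Gordon
parameter `u = bb/(a+bb)`, `kd = (a+bb)/μs'` is the diffuse attenuation,
`z` is depth, `μs'`, `μv'` are Snell-refracted sub-surface direction
cosines and `Duc`, `Dub` are upward diffusion factors.  The inherent
optical properties are parameterised by three scalars: dissolved-matter
absorption at 440 nm (`G`, exponential spectral decay), phytoplankton
absorption at 440 nm (`P`, tabulated shape), and particulate backscatter
at 400 nm (`X`, power-law spectrum).  The bottom albedo is a fully
constrained linear mixture of benthic endmembers (sand, algae/seagrass,
sediment-rock): `ρalb(λ) = Σ abᵢ·emᵢ(λ)` with `abᵢ ≥ 0`, `Σ abᵢ = 1`.

Band-integrating through the sensor's spectral responses yields six
equations per pixel in seven unknowns `(G, P, X, z, ab₁..ab₃)` plus the
sum-to-one constraint.  The system is inverted by damped least squares on
the relative spectral misfit `δRrs = n·Σ(Rrs_model − Rrs_obs)²/ΣRrs_obs`,
with depth initialised from the blue/green log-ratio heuristic.

Around the inversion the package provides radiometric calibration,
algebraic atmospheric correctors in three standard forms (FLAASH-, ATCOR-
and 6S-shaped, driven by externally supplied coefficient tables) with
RMSE/BIAS match-up evaluation, NIR-excess sunglint removal integrated
with the water model, SVM benthic classification with Jeffries–Matusita
separability screening, and a deterministic synthetic-scene generator
that produces full ground truth.

## Worked example

```python
import numpy as np
import shallowsea as ss

# a 32x32 synthetic coast: depth ramp 0.5-15 m, random IOP fields,
# per-pixel random benthic mixtures, deterministic for the seed
cfg = ss.SceneConfig(shape=(32, 32), seed=1, depth_kind="gradient")
truth = ss.generate(cfg)

# invert the six optical bands per pixel
res = ss.invert_scene(truth.observed[:6], cfg.geometry, truth.lib,
                      truth.bands.subset(6))

rel = (res["z"] - truth.z) / truth.z
print(f"depth rel. RMSE: {100*np.sqrt(np.mean(rel**2)):.2f}%")
print(f"abundance RMSE:  {np.sqrt(np.mean((res['abundance']-truth.abundance)**2)):.4f}")
```

prints (exact values depend on the seed):

```
depth rel. RMSE: 0.52%
abundance RMSE:  0.0035
```

i.e. on a noiseless scene the inversion recovers bathymetry to well under
a percent and benthic fractions to a few thousandths — the residual error
comes from the handful of pixels where six bands cannot uniquely separate
a dark bottom from deeper water.

The same chain is available from the shell:

```sh
shallowsea simulate --out scene/          # synthetic scene + ground truth
shallowsea deglint  --input scene/observed.tif --out deglinted.tif
shallowsea invert   --input deglinted.tif --out retrieval/
shallowsea endmembers                     # inspect the spectral library
```

See `examples/` for short narrative scripts covering each capability
(atmospheric correction and match-up scoring, unmixing, deglinting,
inversion, classification).

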