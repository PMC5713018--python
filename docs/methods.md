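# Methods

This note records the models implemented in `shallowsea`, the defaults
chosen where the underlying literature leaves the design open, and what
the synthetic test bed does and does not establish.

## Water-column optics

Absorption is `a(λ) = aw(λ) + aph(λ) + adg(λ)` with

* `aph(λ) = (a0(λ) + a1(λ)·ln P)·P`, `P = aph(440)` in m⁻¹.  The shape
  coefficients `a0, a1` are bundled (Lee-style parameterisation,
  normalised so `a0(440)=1, a1(440)=0`, zero beyond 720 nm).  `P = 0` is
  handled as `aph ≡ 0`, the `P·ln P → 0` limit.
* `adg(λ) = G·exp(−Sg·(λ−440))`, `G = adg(440)` in m⁻¹.  The slope `Sg`
  defaults to 0.015 nm⁻¹ and is validated against the physically
  plausible range 0.01–0.03 nm⁻¹.

Backscatter is `bb(λ) = bbw(λ) + X·(400/λ)^Y` with `X = bbp(400)` in m⁻¹.
The two reference wavelengths deliberately differ (440 nm for dissolved
matter, 400 nm for particulates), following the conventions of the
respective sub-models.  The exponent `Y` is fixed at 1.0 rather than
estimated: with six bands and seven unknowns the system is already at
the edge of identifiability, and `Y` produces almost no independent
gradient.  `Sg` is fixed for the same reason.

Pure-seawater `aw`/`bbw` tables are bundled at 5-nm step over
400–1050 nm, assembled from standard published values (`bbw` as a
Morel-style power law with `bbw(400) = 0.0038` m⁻¹).  The near-infrared
`aw` values are approximate; water there is effectively opaque at the
depths considered, so retrievals are insensitive to them.  All tables
are plain TSV and swappable.

## Shallow-water reflectance

The two-stream semi-analytical form mixes the optically-deep reflectance
with the bottom albedo, each attenuated along its effective two-way
path.  Choices the source literature leaves open:

* **Diffusion factors.** `Duc = 1.03·(1+2.4u)^0.5` and
  `Dub = 1.04·(1+5.4u)^0.5`, the standard semi-analytical closed forms
  for the water-column and bottom streams; constants are module-level
  and overridable.
* **Sun/view factors of the deep-water polynomial.** Implemented as
  divisions, `(1+0.1098/μs')·(1+0.4021/μv')`: the product form would
  make reflectance *decrease* toward grazing geometry, which is
  unphysical.  A `angle_mode="multiply"` switch preserves the
  alternative reading.
* **Diffuse attenuation.** `kd = (a+bb)/μs'` with the Snell-refracted
  (n = 1.34) sub-surface solar cosine, dimensionally consistent with the
  attenuation exponent.
* **Air–water interface.** The inversion fits above-surface
  `Rrs = 0.5·rrs/(1−1.5·rrs)` by default; `interface_transfer=False`
  fits sub-surface `rrs` directly, since the source processing level is
  ambiguous.  Corrected-image reflectance ρ is converted by `ρ/π`
  upstream of the fit.

## Per-pixel inversion

Seven unknowns, six band equations, plus the abundance sum-to-one
constraint.  The simplex is parameterised by stick-breaking fractions
`(f1, f2) ∈ [0,1]²` — a smooth bijection that enforces both constraints
exactly — leaving a 6-parameter bound-constrained problem
(`G, P, X ∈ [0, 5]` m⁻¹, `z ∈ [0, 33]` m) solved with scipy's
trust-region-reflective damped least squares using the model's exact
analytic Jacobian.  Convergence: relative cost change < 1e-8 or step
norm < 1e-10, at most 200 iterations.  Initialisation: `z` from the
blue/green log-ratio heuristic (`z₀ = m1·ln(n·B)/ln(n·G) − m0`, defaults
m1 = 25 m, m0 = 20 m, n = 1000, calibratable against depth truth points;
out-of-domain pixels fall back to 2 m and are flagged), `G = P = 0.05`,
`X = 0.01`, uniform abundances.

The misfit surface has multiple regional minima — six noiseless band
values can be fitted *exactly* by more than one parameter set,
typically a dark-bottom/deeper-water ambiguity.  Two measures address
this at scene level:

1. **Multi-start refits.** Pixels whose first-pass cost exceeds
   `min(95th percentile, 10× median)` of the scene costs, or whose depth
   departs from the 3×3 median-filtered depth by more than
   `max(1 m, 35%)`, are re-fitted from the neighbourhood depth, from
   near-vertex abundance starts, and from ×0.5/×2 depth jitters.
2. **Spatially informed tie-break.** Among candidate fits the lowest
   cost wins; costs that tie to numerical precision are broken toward
   the spatially consistent depth (a 1e-10-weighted penalty that is
   negligible whenever real misfit differences exist).

Everything is deterministic given inputs and options; the restart
schedule is fixed, and the configured seed is only recorded in run
metadata.  Pixels that hit the depth bound, fall back on the ratio
heuristic, or fail to converge carry flag bits; non-convergence returns
the best-so-far solution, never an exception.

## Atmospheric correctors and match-ups

The three correction forms are *algebraic* inverses driven by per-band
coefficient tables; generating those coefficients with an atmospheric
RTC is out of scope.  The neighbourhood reflectance ρe uses a box mean
of radius 10 px (edge-replicated) by default — no kernel is prescribed
by the correction forms themselves.  The ATCOR-form adjacency step is
`ρ ← ρ + q·(ρ−ρe)` with `q = 0` (off) by default, as no closed form is
prescribed.  Out-of-range reflectance is logged, never silently clipped.
Match-up scoring uses the mean over a 3×3 window per site; BIAS is
`mean(ρ_insitu − ρ_sat)`, so negative BIAS flags overestimation by the
correction.

## Sunglint removal

Per visible band, the ordinary least-squares slope against the NIR over
a sample region spanning variable glint; the correction subtracts
`b·(NIR − baseline)` where the baseline is the larger of the
forward-modelled water-leaving NIR and a low percentile (default 2nd) of
the observed NIR — so shallow/turbid scenes with genuine NIR signal are
not over-corrected.  The NIR band itself is replaced by the baseline
(configurable), which makes the correction idempotent.  Negative results
are floored at zero and counted in the log.

## Classification

Features are the retrieved abundances plus bathymetry (depth stratifies
several habitat classes).  Separability: Jeffries–Matusita under
Gaussian class models with a 1e-6 ridge on covariances.  Classifier:
one-vs-one RBF SVM, γ = 0.25, C = 100, on features z-scored by the
training statistics (the fixed γ presumes comparable feature scales).
Map quality: ground-truth-percent confusion matrix, overall accuracy,
Cohen's kappa.  `reconstruct_truth_proportions` inverts a *published*
column-normalised matrix plus its "% of Total" shares back to the truth
proportions and the overall accuracy they imply, flagging tables whose
reconstruction residual exceeds 1%.

## Synthetic scenes

The generator emulates a WV-2-class 8-band sensor over a shallow coast:
depth fields (constant / shore-to-sea gradient / Gaussian-smoothed
random), IOP fields within `G ∈ [0.01, 0.3]`, `P ∈ [0.005, 0.2]`,
`X ∈ [0.001, 0.05]` m⁻¹, benthic cover as per-pixel random simplex draws
or a Voronoi patch mosaic of named classes, sinusoidal glint streaks
with per-band slopes near one and zero-glint troughs, and
multiplicative/additive noise.  Observations are produced by exactly the
forward operator the inversion fits, so recovery experiments isolate the
inversion itself.  Default scene sizes in the tests and acceptance runs
(64×64 for recovery, 48×48 for the end-to-end mosaic, 40×40 for
deglinting) are large enough for stable scene statistics while keeping a
full run in the minutes range on one CPU.

The bundled endmember library is *synthetic*: three spectra shaped to
the qualitative field description (bright sand rising toward the red;
dark, flat sediment-rock; vegetation with a green peak, chlorophyll
trough and red edge).  It is a fixture, not measured data, and users
substitute measured libraries via the same TSV format.

What passing the synthetic tests does **not** establish: performance
under real sensor noise models, atmospheric-correction residuals,
endmember libraries that mismatch the true bottom, BRDF bottom effects,
vertically stratified water, or wave focusing.  The generator's bottom
and water are exactly the inversion's model family; real-scene accuracy
is bounded below by these results, not established by them.

## Known limitations

* Six bands cannot always uniquely identify seven parameters: isolated
  exact ambiguities persist (order 0.1% of pixels on noiseless scenes)
  and are resolved only by the spatial-consistency tie-break.
* Abundance accuracy degrades with depth as the bottom term is
  attenuated; beyond ~10–15 m the abundances become uninformative while
  IOPs remain retrievable (the depth bound flag marks such pixels).
* The printed reference confusion matrix used in the reconstruction
  check is internally inconsistent with its own stated kappa; only the
  ">90% overall accuracy" bound is asserted.
* GeoTIFF georeferencing travels in a JSON sidecar rather than embedded
  geo-tags.
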