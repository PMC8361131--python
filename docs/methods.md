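# Methods

This note documents the models and numerical choices behind `metalsense`:
what the synthetic stimuli emulate (and deliberately do not), how the
image statistics are computed, how the simulated psychophysics and
maximum-likelihood fits are parameterized, and where the design was
genuinely open.

## The stimulus model

The target of the emulation is a rendered object — a metal core under a
smooth dielectric coating, lit by a natural environment, floating on a
black background — whose two physical parameters are metal roughness
(which blurs the reflected environment) and coating bump strength (which
refracts, i.e. spatially distorts, the image formed beneath the
coating). The generator reproduces the *statistical* structure of such
images, not their geometry:

* **Base image.** Random-phase noise with an *exact* amplitude spectrum
  ∝ 1/f<sup>e</sup> (default e = 1, the slope regime of natural images;
  only the Fourier phases are random, so all views share one spectrum).
  The field is standardized **within the object mask** and passed
  through the point nonlinearity `exp(skew·z)` (default skew 1), giving
  a positively skewed, high-dynamic-range luminance distribution whose
  sparse bright tails play the role of specular highlights; `skew=0`
  selects the identity (a symmetric control). In-object mean luminance
  is then normalized to 1: views emulate *rotations of one object under
  one illuminant*, so they must agree in their in-object luminance
  moments and differ only in spatial arrangement. Without this
  normalization, between-view variance of the global statistics swamps
  the condition effects — something object rotations in a fixed
  environment do not do.
* **Object mask.** A boolean blob: a centered disc (radius 0.38 ×
  image size) with three seeded low-order radial harmonics. The mask is
  identical across views and conditions — the silhouette belongs to the
  object's shape, which neither axis manipulates.
* **Smoothness axis.** Mask-normalized Gaussian blur of in-object
  content (`blur(L·M)/blur(M)` inside the mask): the silhouette stays
  sharp, a constant surface stays constant, and only the "reflected
  environment" is smoothed. Default sigmas are linearly spaced from 0
  to image_size/64 px. The upper end matters: beyond roughly
  image_size/50 the finest pyramid level is dominated by the fixed
  silhouette edge and the smoothness code A₁ saturates.
* **Bumpiness axis ("local disarray").** A divergence-free displacement
  field — the rotated gradient of a Gaussian random field smoothed to
  correlation length image_size/128 px — rescaled to RMS displacement
  equal to the level's amplitude (default 0 to 3·image_size/64 px),
  applied by *nearest-neighbour* resampling with out-of-object source
  positions filled by the nearest in-object value. One field is drawn
  per view and scaled by the amplitude: the same coating geometry at
  increasing bump depth. The resampling is a near-permutation of pixel
  values, so it creates the fine shear edges a refracting bumpy coating
  introduces (raising the finest-level pyramid response) while leaving
  the luminance histogram essentially unchanged — which is exactly why
  histogram-shape statistics (skewness, dynamic range, Michelson) are
  blind to this axis. After resampling, the in-object mean is restored
  (refraction redirects light, it does not absorb it) and the image is
  attenuated by the scatter-loss gain `1 − 0.85·amplitude/image_size`
  (≤ 5 % at the top level): the fraction of light a bumpy coating
  scatters out of the specular path. The gain is the sole mechanism by
  which bumpiness lowers variance-type contrast (RMS, local image
  contrast, Meese–Summers), and — being a pure scale factor — it leaves
  every scale-invariant statistic untouched.

  Two alternatives were rejected during design: bilinear interpolation
  (its resampling loss makes the fine/coarse ratio *fall* at small
  amplitudes before rising, destroying monotonicity), and warping with
  out-of-object samples set to 0 (which injects spurious zeros into the
  luminance sample, making ratio statistics degenerate and shifting the
  in-object mean by far more than the warp itself).
* **Composition.** Blur first, then disarray: in the physical stimulus
  the rough metal blurs the reflection *beneath* the coating that then
  distorts it.

What the generator does **not** emulate: geometric perspective and
shading of a 3-D object, the shared content of true rotations (views
here are content-independent), chromatic information, and any
calibrated mapping from physical roughness/bump units to pixel units.
Consequently, passing tests show that the *pipeline* behaves correctly
on images with the right statistical signatures; they do not certify
numeric agreement with measurements on rendered or photographed
stimuli.

## Image statistics

* **Radial power spectra.** Images are windowed (2-D Hann by default;
  the window is a recorded choice, not a constant) and the power
  spectrum |FFT|²/N is distributed onto integer cycles-per-image bins by
  linear (inverse-distance) interpolation between the two neighbouring
  bins; corner samples beyond the Nyquist ring pool into the Nyquist
  bin, so binned power × bin area conserves total non-DC energy to
  well within 2 %. Spectra are computed whole-frame (the black
  background contributes nothing but the silhouette edge); a
  mask-restricted variant was considered and left out as the original
  processing is unstated. The 23–53 cpi band mean is the scalar used to
  compare smoothness levels; the log–log slope is fit by least squares
  over 4 cpi to a quarter of the image size.
* **Steerable pyramid.** Frequency-domain construction: raised-cosine
  radial masks with one-octave log-frequency transitions, angular masks
  |cos|^(K−1) normalized so the squared masks tile the plane, recursive
  lowpass + spectrum-crop downsampling with the unitary amplitude
  convention (×1/2 per crop), giving a tight frame — subband energies
  sum to image energy and reconstruction is exact to machine precision,
  which the tests use as an oracle. Four levels × four orientations by
  default; level 1 is the finest.
* **Level activations.** `A_l = ln(Σ_orientations mean|coefficient|)`.
  Mean absolute pooling was chosen over variance for robustness to the
  sparse highlight tails; natural log throughout (the base is
  immaterial but fixed). An all-zero level yields −∞ with an explicit
  degeneracy flag rather than a silent NaN. The two model-observer
  statistics are `A₁` (smoothness: blur attenuates fine detail) and
  `A₁ − A₄` (bumpiness: a log fine/coarse ratio, exactly invariant to
  global luminance scaling and empirically far less view-sensitive
  than either level alone).
* **Contrast estimators.** All nine are computed over the object mask
  only (the black void makes extrema-based measures degenerate
  otherwise). Population (1/N) moments throughout. The summation forms
  (LIC, Meese–Summers) default to the mean (1/N) normalization so
  values are resolution-invariant; a flag restores raw sums. The
  blurred reference B for the *blur* variants is a mask-normalized
  Gaussian blur with sigma = image_size/4: wide enough that B
  approximates the global in-object mean and is insensitive to
  pixel-scale disarray — with a narrower reference (image_size/8) the
  shuffle component of the warp inflates |L−B| and masks the
  scatter-loss contrast reduction.

## Simulated tasks and fitting

* **Designs.** Conjoint measurement: all unordered pairs of grid
  conditions including identical pairs (they differ by view) — 325 for
  5×5 — each repeated 4 times with views drawn without replacement
  (never equal within a trial), 1300 trials per session. Difference
  scaling: all C(n,4) non-overlapping quadruples a<b<c<d of one
  dimension's levels (330 for 11) with four distinct views per trial;
  a seeded uniform subsample supports designs that used a reduced
  count (e.g. 310 — the original exclusion rule behind that number is
  not derivable from the standard rule, so it is provided as an option
  rather than guessed).
* **Observers.** Decision variable = statistic difference + Gaussian
  noise; ties (possible only at zero noise) break by a fair coin from
  the observer's stream. Simulation noise defaults to 0.1 × the
  statistic's range over the stimulus set, which yields fitted scales
  of a few d′ — the magnitude regime of practiced human observers.
* **Fitting.** Both tasks are Bernoulli probit models fit by L-BFGS-B
  on the exact negative log-likelihood with analytic gradients, with
  the standard identifiable parameterization: first level (or cell)
  anchored at 0, decision-noise SD fixed at 1, so estimates are d′
  values. Parameters are box-bounded at ±10 d′; estimates at the bound
  trigger a separation warning instead of diverging. MLDS uses the
  signed-difference linearization (exact when the fitted scale is
  monotone, which every simulated regime here satisfies); a direct
  Nelder–Mead optimizer over the non-smooth absolute-value likelihood
  is available as a cross-check and fallback. The independent conjoint
  model fits either dimension; `'auto'` keeps the better likelihood.
  Likelihood-ratio statistics are clipped at 0 against optimizer noise
  and referred to the chi-square with df = parameter-count difference.
  Bootstrap intervals are case-resampling percentile intervals;
  cross-observer averaging divides each observer's pooled scale vector
  by its RMS before averaging (the normalization rule is a package
  choice — only "normalized" is specified in the tradition this
  follows).
* **Metallicity weights.** `m = a·A₄ + b·A₁` is fit to an observer's
  conjoint scale by least squares of the additive cell values
  ψ_S(i)+ψ_B(j) on the view-averaged activations (Ā₄, Ā₁) with a free
  intercept absorbing the anchoring — deterministic and closed-form. A
  simulate-and-refit route exists as a cross-check. Because the
  conjoint scale is in units of the observer's decision noise, weights
  are identified up to that scale: the *direction* of (a, b) is the
  meaningful quantity. View-averaged activations are used because the
  model's job is view-robust prediction; per-view and
  intercept-free variants are exposed through the activation table and
  fit inputs.

## Problem sizes

The test suite and the acceptance script synthesize stimuli at 256 px
(design-count checks at 32 px), with the size-relative parameter
defaults above; statistical checks use 5–20 Monte-Carlo replicates,
the bootstrap coverage study 200 replications × 200 resamples on a
reduced 3×3 design at 8 repeats. These sizes keep a full run in
minutes while leaving every probability and monotonicity check far
from its numerical floor.

## Known limitations

* The disarray transform is calibrated to reproduce qualitative
  image-statistic trends, not any physical bump-height scale; absolute
  statistic values are not comparable to rendered stimuli.
* Views are statistically matched but content-independent; analyses
  that rely on partial content overlap between rotations (e.g.
  pixel-level view matching) are out of scope by design.
* The signed-difference MLDS linearization assumes a monotone scale;
  for strongly non-monotone observers use `method="direct"`.
* Percentile bootstrap intervals slightly undercover at small trial
  counts (the coverage study runs at 360 trials for this reason).
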