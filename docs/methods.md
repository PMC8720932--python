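# Methods

This note records the models, conventions and numerical choices behind
`chromastress`, and what its synthetic validation does and does not
establish.

## The color metric

The metric is the mean, over all pixels of a 256×256 chromaticity field,
of each pixel's mean Euclidean (u′, v′) distance to its existing
8-connected neighbors (3 at corners, 5 on borders, 8 in the interior).
Conventions fixed here:

* **Working space.** sRGB with D65 white (IEC 61966-2-1 primaries and
  transfer function), reference white Y = 1. The metric depends only on
  chromaticity ratios, so the luminance scale is a convention.
* **Downsampling.** Nearest neighbor with the half-pixel-center index
  map `src = floor((dst + 0.5)·in/out)`, clamped. No new pixel values
  are invented and aspect ratio is not preserved (very wide scenes are
  legitimately mapped to 256×256). Inputs not larger than 256 in either
  dimension — notably 256×256 patches — are used as-is; `resize=False`
  forces this.
* **Black pixels.** u′v′ is 0/0 at black; pixels with X+15Y+3Z < 1e-9
  are assigned the D65 white-point chromaticity. Any constant
  assignment gives the same metric for all-black regions bordered by
  black; white avoids spurious chromatic edges at dark pixels. Other
  toolboxes may resolve this degeneracy differently; for ordinary
  photographs the affected pixels are rare.
* **Averaging weight.** The image value is the unweighted mean of
  per-pixel d_px, so border pairs carry slightly different weight than
  interior pairs; it is *not* a mean over unique pixel pairs.
* **Precision.** Double precision throughout; display rounding to 4
  decimals only at presentation time.

Closed forms used as oracles: for a 1-pixel two-color checkerboard the
interior d_px is d/2 (4 of 8 neighbors differ), so the image metric tends
to d/2 as size grows; for 1-pixel vertical stripes interior d_px is
exactly 6d/8; a 2×2 split field gives 2d/3 at every pixel.

## Luminance metrics

The departure-from-1/f^α measure is a **documented approximation**: the
radial Fourier amplitude spectrum (mean-subtracted, amplitudes binned by
integer radius, DC excluded) is fitted with log a = c − α·log f by least
squares over radial frequencies from 2 cycles/image to the Nyquist bin,
and the departure is the RMS residual in log-amplitude units. The
published contrast-sensitivity-weighted discomfort measure it stands in
for has no public formula; this construction preserves the construct
(deviation from the natural spectral regularity) but its numbers are not
comparable to that measure's. No window is applied by default (a Hann
window is available via a flag).

Luminance edge energy reuses the metric's neighbor-averaging scheme on
the scalar luminance plane. Because chromatic transforms never touch L,
edge energy is invariant under them by construction — this is asserted
exactly, and is what makes triples luminance-matched.

## Chromatic transforms and triples

A transform maps chromaticities c → pivot + s·R(θ)(c − pivot). A pure
rotation is an isometry of the (u′, v′) plane and leaves the metric
unchanged; radial scaling multiplies it by exactly s (field level).
"Pseudo-rotation" is here interpreted as rotation combined with such
scaling — the minimal extension that can move the metric between target
levels. The default pivot is the D65 white point. The default bank is a
deterministic 35 angles × 10 scales grid (s ∈ [0.15, 2.2], the grid
point nearest 1 snapped to 1 so the identity is a member), 350 specs in
total. On inversion to sRGB, out-of-gamut chromaticities are shrunk
toward the pivot at constant luminance by binary search (40 iterations);
the clipped-pixel fraction is recorded per triple member and a warning
is logged above 10%.

Triples select, for each of the three target levels (defaults 0.0035,
0.0115, 0.0190 — the lower end, mean and upper end of an uncomfortable
art-stimulus distribution), the bank transform whose achieved metric is
closest to the target; images missing any target by more than the
tolerance (default 0.002) are skipped with a logged reason. The
procedure is deterministic.

## Natural-scene statistics

The corpus distribution keeps the raw sample moments (mean, SD with n−1)
— these feed the z-scores — plus a Gaussian KDE with Silverman bandwidth
for display only. Rectified z-scores are max(0, (x − μ)/σ): only
positive deviations from nature are allowed to predict discomfort. The
shift analysis moves the reference mean by δ with σ unchanged (a rigid
shift along the metric axis) and tracks the Spearman correlation between
the rectified scores and mean discomfort, with percentile-bootstrap CIs.
When a shift rectifies every stimulus to zero the correlation is
undefined and recorded as NaN, never as 0. Calibrated scene sets that
carry a gray calibration ball in the left third of the frame are cropped
with `crop_left_third` before metric computation.

## Mixed models and inference

Ordinal 1–5 ratings are treated as numeric in a Gaussian linear mixed
model (the standard lmer-style analysis for such data). The default
random structure is a correlated per-observer random intercept and
random slope for each metric covariate; with one covariate this makes
the null-vs-full likelihood-ratio test df = 3 (fixed slope + slope
variance + intercept–slope covariance). Covariates are z-scored across
images before fitting, with raw-unit slopes also reported. Fits are ML
(not REML) so nested fits feed LRTs; AIC = 2k − 2ℓ with k counting fixed
effects + free (co)variances + the residual variance.

Numerical choices that matter:

* **Optimization.** statsmodels' MixedLM can return spurious infinite
  likelihoods or stop at poor local optima when a variance component
  sits at the boundary. Random-slope fits therefore try lbfgs, bfgs and
  powell and keep the best finite log-likelihood; additionally the
  intercept-only-RE solution of the same formula — a boundary point of
  the slope model's parameter space — is fitted, and adopted whenever
  its likelihood is higher (the parameter count of the full structure is
  kept). Singular random-effect covariances are flagged with a warning.
* **Confidence intervals.** Fixed-effect 95% CIs use a t quantile on
  (number of observers − 1) degrees of freedom rather than the Wald
  normal quantile, which is anticonservative with tens of observers
  (the motivation behind Satterthwaite/Kenward-Roger corrections).
* **Testing a fixed effect.** The calibrated test of β = 0 keeps the
  covariate's random slope in *both* models (df = 1, interior
  hypothesis). The joint df = 3 test that also removes the random slope
  involves a variance component on the boundary of its space; its LRT
  against χ²₃ is conservative (simulated rejection ≈ 0.01 at nominal
  0.05), which is expected behavior, not an implementation defect.
  LRT statistics within 0.01 of zero are clamped to 0; clearly negative
  values raise, as they indicate non-nested models or failed fits.
* **Tukey contrasts.** Pairwise level differences use the single-step
  adjustment: each adjusted p is 1 − P(max|Z| ≤ |z|) under the joint
  normal distribution of the standardized contrasts (multivariate
  normal CDF), the same procedure multcomp applies to general parametric
  models.
* **Bootstrap.** Spearman CIs are percentile CIs over paired item
  resamples (images, not observers), default B = 10,000, seeded. The
  correlation-difference test resamples the same items into both
  correlations; its two-sided p is the fraction of resampled
  differences on the far side of 0 from the observed difference,
  doubled and capped at 1. Undefined correlations (all ties) propagate
  as NaN.

## Synthetic data: what it emulates, and what it does not

* **Two-color patterns** exercise the metric's closed forms.
* **Fruit scenes** place disks of one chromaticity on a differently
  colored background under an independent 1/f luminance texture: local
  chromaticity difference concentrates on the disk outlines, the
  qualitative signature of fruit-against-foliage patches. The default
  luminance texture spans [0.10, 0.40] because the default red-fruit
  chromaticity leaves the sRGB gamut above L ≈ 0.40.
* **Corpora** are white-point-centered Gaussian chromatic noise fields
  whose metric scales linearly with the noise spread; a 20-point
  monotone spread→metric lookup (rebuilt per image size, cached) inverts
  per-image targets drawn from N(μ, σ). Defaults target the
  natural-scene reference moments μ = 0.0056, σ = 0.0023; realized
  moments land within a few percent of the mean and ~10% of the SD at
  n = 200.
* **Observers** follow a linear latent model: intercept_o +
  slope_o·z(metric) + ε, with (intercept_o, slope_o) bivariate normal
  and the latent value rounded and clamped to 1–5. Defaults: β = 0.3,
  grand mean 2.5, SD_intercept 0.5, SD_slope 0.2, ρ = 0, SD_ε = 0.7 —
  between-observer slope spread comparable to what rating studies
  report, grand mean in the low-discomfort range typical of art
  stimuli.

None of these generators produce natural images: corpora are noise
fields without spatial chromatic correlation, scene content, or
photographic gamut structure. Passing tests therefore establish the
*internal* correctness of the metric, the transforms and the inference —
oracle agreement, invariances, calibration, parameter recovery — not
that real scenes or real observers behave like the generators.

## Validation protocol sizes

Simulation sizes are chosen to run on one CPU core in a few minutes:
slope recovery uses 100 replicates of 25 observers × 30 corpus images
(48×48); the LRT calibration 200 replicates of 20 observers × 30 images;
bootstrap CI coverage 500 replicates at n = 50 with B = 1000. The
round-and-clamp discretization attenuates the fitted slope by roughly
5%, which is negligible relative to sampling error at these sizes but
would dominate CI coverage at much larger designs; an ordinal-response
model would remove it and is out of scope.

## Known limitations

* No ICC profiles, chromatic adaptation, or HDR input; sRGB only.
* No perceptual-uniformity correction beyond u′v′ (no CIEDE2000).
* The exact grid of chromatic transforms behind published 350-transform
  stimulus sets is unpublished; the bank here matches the count and the
  constant-luminance construction, not necessarily the original specs.
* The Gaussian treatment of ordinal ratings is the field's standard but
  remains an approximation (see attenuation above).
* The random-effects structure of triple designs (observer + triple) is
  implemented as a variance component nested within observers, which
  approximates, not reproduces, a fully crossed design.
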