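# Methods

This note documents the models, parameter choices and numerical design of
`ramanclear`: what each stage assumes, which defaults matter, and what the
synthetic-data tests do and do not demonstrate about real measurements.

## Spectrum model and preprocessing

A spectrum is a strictly increasing wavenumber axis with matched intensity
counts, tagged with region (fingerprint, FP, 400–1800 cm⁻¹; high
wavenumber, HWN, 2600–3800 cm⁻¹), probing depth (µm) and treatment time
(s).  Untreated references carry `time_s=None` rather than 0, because "no
agent applied" and "measured at the instant of application" are different
physical states.  Wavenumber grids are never interpolated implicitly;
`resample_to_grid` must be called explicitly.

Preprocessing order is baseline → Savitzky–Golay smoothing → optional PCA
denoising.  Within a run every spectrum is processed with identical
parameters, because the clearing-efficiency ratio only cancels instrument
and preprocessing factors that are applied uniformly.

**Fingerprint baseline.**  An iterative lower-envelope polynomial:
anchor points are seeded from a rolling lower-quantile envelope
(`anchor_quantile`, default 0.1) so peaks are excluded from the first
fit, then the anchor set is re-estimated against the current fit (points
not more than 2.5 fitted-σ above it) until stable.  Defaults: order 5
for FP spectra.  On a pure polynomial of degree ≤ order the subtraction
is exact; a narrow peak on a flat baseline is preserved to better than
2%.

**High-wavenumber baseline.**  The OH-stretch envelope occupies most of
the HWN axis, so a lower-envelope method would swallow the broad water
bands.  `subtract_hwn_baseline` instead fits the polynomial (default
order 2) only inside the signal-free edge windows 2600–2700 and
3750–3800 cm⁻¹.  Higher orders are deliberately avoided: with anchors
only at the two edges, a cubic's interior is poorly constrained and a
~0.05-count contamination in the windows can bow it by an order of
magnitude more in the middle.

**Smoothing.**  Standard Savitzky–Golay, default 11-point window, 3rd
order.  The filter reproduces polynomials of degree ≤ 3 exactly; it
attenuates a σ ≈ 6 cm⁻¹ Gaussian peak by ~0.6%, which cancels in every
ratio-based quantity and in calibration provided standards and samples
are smoothed identically.

**PCA denoising.**  Spectra sharing one axis are mean-centred, decomposed,
and rebuilt from the top components (default 3).  At full rank the
operation is the identity.  Whether denoising is grouped per depth, per
region or globally is an analysis choice the library leaves to the
caller; the pipeline default is no PCA (the step is exposed but not
forced), since band-maximum extraction after baseline and smoothing is
already robust at the noise levels studied.

**Band intensity** is the maximum baseline-corrected intensity within
±10 cm⁻¹ (configurable per band) of the nominal center, reported together
with the wavenumber at which it was found.  A peak maximum was chosen
over an integrated area because it is insensitive to the window width and
to residual baseline curvature; since every downstream quantity is a
ratio or a calibrated linear map, the choice of metric cancels as long as
it is used consistently.  The two amide III bands (1247, 1270 cm⁻¹) are
stored at one canonical center each; the ±10 cm⁻¹ window absorbs ±1 cm⁻¹
reporting differences.

## Calibration

Unweighted ordinary least squares of the glycerol 485 cm⁻¹ band intensity
against volume fraction (0–50%, 15 standards).  The inverse map clamps
negative predictions to 0% and flags them — noise around zero glycerol in
deep layers is expected and should not abort a pipeline.  There is no
upper clamp.

## Clearing efficiency and the reconstructed glycerol signal

`OC_eff = I_OC / I_0` per collagen band, depth and time, with `I_0` taken
from the averaged untreated spectra of the *same* sample and depth (never
a population mean — the correction is local by construction).
`TRGC = I_gly / OC_eff` removes the inflation of the glycerol band caused
by clearing of the overlying layers; multiplying all intensities at one
time point by any factor leaves TRGC unchanged, which is the correction's
defining invariant and is verified exactly in the tests.

TRGC is computed per collagen reference band and carried separately
through the diffusion fit; per-depth D and C₀ are averaged *after*
fitting.  Averaging OC_eff across bands first would discard the per-band
spread that the per-depth average row is meant to summarise.

## Diffusion model

One-dimensional diffusion into a semi-infinite medium with a constant
surface concentration:

    C(x, t) = C0 · erfc( x / (2 √(D t)) ),

with C(x, 0) = 0 for x > 0 and C(0, t) = C₀.  Depths are stored in µm
and converted to cm internally; D is reported in cm²/s.

**Oracle.**  An explicit forward-time centred-space solver on a domain of
depth ≥ 10·√(D·t_max) (far boundary held at 0) cross-checks the closed
form; auto-chosen grids use r = D·Δt/Δx² = 0.4 and a user-supplied grid
violating r ≤ 0.5 raises.  On the study grid (C₀ = 20%, D = 10⁻⁵ cm²/s,
depths 50–200 µm, t ≤ 390 s) the two agree to < 0.001 concentration
points.

**Fitting.**  Least squares with D on a log₁₀ scale, bounds
D ∈ [10⁻⁸, 10⁻³] cm²/s and C₀ ∈ [0, 60]%, multi-started from
D ∈ {10⁻⁶, 10⁻⁵, 10⁻⁴} with C₀ initialised at the series maximum; the
lowest-residual solution is kept.  The log parameterisation matters: the
erfc argument is ill-conditioned in D when x/(2√(Dt)) is small.  Standard
errors come from the Jacobian at the optimum (delta method for D).  The
t = 0 point (concentration 0) is included as an exact model point.
A series that never rises above zero returns a degenerate C₀ = 0 result
rather than raising; a series that declines after its maximum is fitted
as-is and flagged `non_monotone` — the erfc model saturates and cannot
represent a late decline (tissue swelling/rehydration), so the residual
carries it.

**Identifiability.**  With C₀ ≈ 20% and 2% multiplicative noise, 100-
replicate studies at 100 and 150 µm recover D with ≈ 5–9% median error
and C₀ with < 1%.  When the saturation concentration is small (≲ 3%, as
in the deeper layers of the default synthetic conditions), the
band-extraction noise is comparable to the whole signal and D becomes
essentially unidentifiable even though C₀ is still recovered well; the
fit then reports large per-band scatter, mirroring the order-of-magnitude
per-band spread familiar from depth-resolved clearing experiments.  This
is a property of the measurement, not of the optimiser.

**Reporting.**  Per-depth summaries require exactly the five collagen
reference bands and report arithmetic means; report tables round to two
significant figures.

## Water-state deconvolution

Ten Gaussians: lipid/protein 2850, 2880, 2940, 2980; water 3005 (tightly
bound, DAA), 3277 (strongly bound, DDAA), 3458 (weakly bound, DA), 3604
(free); NH 3060, 3330 cm⁻¹.  Free water is represented by the single
3604 cm⁻¹ line (standing for the very-weakly-bound + unbound sum).
"Width" means the Gaussian σ throughout (FWHM = 2.355 σ).  Nominal σ
defaults — 20 cm⁻¹ for the four CH lines, 30 for 3005, 40 for 3060/3330/
3604, 80 for 3277/3458 — follow the OH-stretch deconvolution literature;
centers are bounded at nominal ±5 cm⁻¹ and σ at nominal ±20 cm⁻¹
(floor 2 cm⁻¹), all configurable.  The strongly-bound center is taken as
3277 cm⁻¹ canonically (reported variants 3270/3277 fall inside the
bound).

Ten overlapping Gaussians with free shapes are nearly degenerate:
neighbouring lines can trade area with almost no residual change, and the
unconstrained Cramér–Rao bound on the smallest state's area ratio exceeds
100% at 2% noise.  The fit is therefore a maximum-a-posteriori estimate:
centers and σ carry Gaussian priors at their nominal values (sd 2 and
5 cm⁻¹), weighted by the per-point noise level estimated from second
differences of the spectrum and floored at 0.1% of the signal maximum.
The penalty vanishes as noise → 0 (noise-free recovery is exact to
< 10⁻⁴ relative) and costs nothing when the true shapes are nominal; on
real tissue it encodes the same prior knowledge that leads practitioners
to fix line positions.  Initialisation is deterministic — non-negative
linear least squares for amplitudes with shapes held at nominal — so the
decomposition is bit-for-bit reproducible.  Non-convergence returns the
best attempt flagged, never an exception.

Each water state is quantified as its Gaussian area (closed form
A·σ·√(2π)) divided by the 2940 cm⁻¹ protein area; total water is the sum
of the four state ratios — an exact identity, tested as such.  Glycerol's
own CH/OH bands overlap this region; no glycerol subtraction is applied
(matching the measurement protocols this pipeline targets, which report
the possible underestimation instead), and an optional glycerol-reference
subtraction hook is left out of scope.  The before/after summary time
defaults to 90 s.

## Synthetic experiment generator

The generator emulates the study design end to end: 15 calibration
standards 0–50%; four depths (50, 100, 150, 200 µm); spectra every 30 s
from 0 to 390 s plus untreated replicates (4 per depth); collagen band
amplitudes multiplied by a saturating clearing gain
g(t) = 1 + (g_max − 1)(1 − e^(−t/τ)) (defaults g_max 2.0/1.9/1.8/1.25 and
τ 45–90 s across depths — the deepest layer clears several-fold less);
glycerol 485 cm⁻¹ amplitude = response × C(x, t) × g(t) with the erfc
profile at per-depth (D, C₀) defaulting to the reported per-depth
averages (9.6×10⁻⁶…3.0×10⁻⁵ cm²/s; 20…0.6%); HWN spectra as the
ten-Gaussian sum with water ratios following an exponential approach from
the reported "before" to "after" values (τ = 30 s).  All line shapes are
Gaussian; noise is multiplicative (cv × signal, default 2%) plus a small
additive floor (0.3 counts); baseline drift is a gentle polynomial.  All
randomness flows from one seeded generator: same seed + spec gives
bit-identical spectra.

What the synthetic tests demonstrate: the pipeline's algebra (crosstalk
cancellation, sum rules, scale invariances) exactly; parameter recovery
at realistic noise; and the qualitative kinetic structure (dehydration of
the mobile water states, concentration rising toward saturation).  What
they do not demonstrate: real spectra have non-Gaussian line shapes,
fluorescence backgrounds, cosmic-ray spikes and sample-to-sample
variability that the generator does not emulate, and the real tissue's
measured kinetics cannot be recomputed from summary tables alone.

## Problem sizes

The default test and acceptance runs use the full study geometry (4
depths × 14 time points, 1 cm⁻¹ FP grid, 2 cm⁻¹ HWN grid), 100-replicate
noise studies for the diffusion fit and 50-seed studies for the
deconvolution — sizes at which every stochastic tolerance is stable from
seed to seed while a complete run stays fast on a single core.

## Known limitations

- The erfc model assumes a constant surface concentration and a single
  transport process; late-time declines (swelling, surface depletion) are
  flagged, not modelled.  A two-process model for the deepest layer is a
  known extension and deliberately out of scope.
- D is reported even where weakly identified (small C₀); consumers should
  consult the standard errors and the non-monotonicity/degeneracy flags.
- The water-state priors bias shape estimates toward nominal when the
  data cannot distinguish alternatives; this is intended, but means σ
  estimates should not be over-interpreted.
- The CLI exposes YAML configuration with programmatic validation
  (messages name the offending field) rather than a formal JSON-schema
  document.
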