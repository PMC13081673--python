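# Methods

This note records the models implemented in `iolsim`, the defaults that
matter, and the choices made where the design was genuinely open.

## Optical primitives

The visual-Strehl proxy used throughout is the single-frequency MTF at
ν = 15 cycles/degree for a 3 mm pupil, normalized by the diffraction
limit.  The defocused single-frequency OTF is computed as the pupil
autocorrelation with a quadratic phase: defocus of Δ diopters over a
pupil of diameter p puts a wavefront sag W20 = Δ·p²/8 at the margin, and
the 2-D overlap integral collapses to a 1-D cosine-weighted chord
integral (the two sheared pupil copies differ by a phase linear in the
shear direction).  The test suite checks this reduction against an
independent 2-D grid autocorrelation.  The monofocal kernel is this
through-focus response rectified at zero (negative lobes are spurious
resolution, not usable contrast) and normalized to 1 at best focus; its
FWHM at the default parameters is ≈ 0.45 D.  A Gaussian kernel with
configurable σ is available as an alternative.

## TFVS estimation

* **Resampling** — linear interpolation onto a uniform 0.05 D grid, the
  same step as the addition grid downstream.
* **Polychromatic weighting** — per-wavelength curves are averaged with
  luminous-efficiency weights 0.11/0.99/0.15 (R/G/B, normalized to sum 1)
  *before* normalization by the diffraction limit at the 555 nm
  reference; broadband ("white") sources are treated as a single 555 nm
  curve with weight 1.
* **Filter** — Kaiser-window FIR to the printed single-pass targets
  (passband 0.05 D⁻¹, stopband 0.5 D⁻¹, 0.05 dB ripple, 10 dB
  attenuation).  The Kaiser method admits a single deviation, so the
  stringent passband requirement governs (δ ≈ 0.0029, ≈ 50 dB), giving a
  ≈ 141-tap filter at 0.05 D sampling.  Because the closed-form tap
  estimate leaves the response marginally outside the passband bound at
  the band edge, the design loop lengthens the filter until an
  independent frequency sweep passes both bounds.  Applied zero-phase
  (forward–backward, reflection padding), which doubles the stopband
  attenuation; curves must span at least one filter length (≈ 7 D at the
  default step) — the packaged designs use a −6 to +2 D grid.
  Normalized values above 1 (digitization noise in real data) are
  clipped with a logged count; values are not re-normalized after
  filtering.
* **Plane conversion** — the scale change from the IOL plane to the
  entrance pupil depends on the pseudophakic eye model and is exposed as
  a single configurable factor, default 1.0 (identity).

## Temporal-coefficient solver

The mixture is solved on a candidate addition grid of −0.50 to +4.50 D in
0.05 D steps (covering vergences +0.5 to −4.5 D).  Two design choices are
central:

1. **Filtered kernels.**  The estimation filter is strong enough that the
   estimated TFVS is a heavily smoothed version of the underlying
   optics.  Fitting it with *raw* monofocal kernels compares unlike
   objects and produces dense, ripple-compensating profiles (20–40
   states) whose reconstructions correlate poorly with the target.  The
   solver therefore fits with the kernel passed through the same
   zero-phase filter — the mixture model seen through the same estimation
   operator as the data.  Profiles become sparse (1–5 states on the
   packaged designs, the monofocal exactly 1), and the fitted curve *is*
   the filtered reconstruction, which is what the estimated TFVS should
   be compared against.  Raw-kernel reconstructions are still used where
   the physical lens output matters (focimetry).

2. **Backward elimination.**  After the initial nonnegative least
   squares, the active coefficient whose removal costs the least residual
   RMSE is dropped and the remainder refitted.  Coefficients below the
   prune fraction (default 1% of the cycle, i.e. dwells under 0.2 ms the
   hardware cannot render faithfully) are always dropped; elimination
   continues beyond that while a step costs at most `rmse_step_tol`
   (default 0.001 VS units).  Eliminating one coefficient at a time is
   deliberate: dropping all sub-threshold coefficients at once and
   refitting can cascade into a useless one-state profile.  At least one
   coefficient is always kept.

Dwell fractions are renormalized to sum to 1; the pre-normalization sum
is kept as the profile's `amplitude` so reconstructions can be placed on
the estimated-TFVS scale.  Ties in support selection are resolved by the
deterministic order of the elimination loop.

## Simulated focimetry and dwell compensation

The tunable lens is modelled as a first-order lag (default τ = 1 ms,
configurable) driven by the commanded 20 ms staircase, states ordered by
ascending addition (the playback order is configurable; the hardware
order is not public).  The power trace (default 100 kHz sampling, four
cycles to reach the periodic steady state) is binned into 0.05 D bins to
give the *effective* dwell profile — the quantity a high-speed focimeter
measures — and the experimental TFVS is reconstructed from it.

An uncompensated lag redistributes enough dwell into transition bins to
violate the validation bounds (peak shift < 0.2 D, RMSE < 0.05 VS) at
τ = 1 ms.  Real temporal-multiplexing systems tune the drive signal
against focimeter feedback, so the pipeline runs a fixed-point dwell
compensation: measure the effective dwell at each commanded state,
rescale the commanded fractions by the shortfall, and keep the iterate
whose reconstruction best matches the nominal one (8 iterations,
commanded fractions floored at two sampling intervals).  With
compensation, all packaged designs validate at τ = 1 ms (RMSE ≤ 0.024,
shift ≤ 0.10 D); at τ = 2 ms the bounds are genuinely not attainable
with dwell rebalancing alone.  Agreement is evaluated within the defocus
range spanned by the profile's additions — outside it the reconstruction
is zero by construction and comparison is meaningless.

## DFVA analytics

* Offset: closed-form mean difference (the exact RMSE minimizer); always
  applied to the simulated curve, never the reference.
* Depth of focus: total measure of all sub-intervals where the linearly
  interpolated logMAR is *strictly* below 0.20, within 0 to −4 D for
  trifocals and 0 to −3 D for EDOFs.  Using the total measure (rather
  than the first-crossing width) handles bimodal curves, which occur in
  practice when residual accommodation adds a secondary acuity peak.
* Benefit/degradation: monofocal minus multifocal logMAR at exactly 0,
  −1.5 and −2.5 D; no extrapolation — missing vergences are reported as
  absent with a warning.
* The cross-correlation is the zero-lag Pearson coefficient (a lagged
  maximum would hide exactly the focus shifts the analysis is after).
  Peak matching pairs every local maximum (≥ 20% of the curve maximum,
  ≥ 5% prominence) of each curve with the nearest maximum of the other,
  so spurious and missing peaks both penalise the peak-shift metric.

## Cohort statistics

* DOF-gain regression: `gain ~ baseline × group + session` with a random
  per-subject intercept, REML via statsmodels MixedLM.  Random intercept
  only — nothing in a two-visit design with one observation per
  subject × lens identifies richer structures.  Slope confidence
  intervals are Wald (±1.96 SE).
* Repeated-measures branch: Shapiro–Wilk at α = 0.05 on doubly-centred
  residuals decides between RM-ANOVA with Bonferroni-corrected paired t
  tests and a Friedman test with Tukey–Kramer post hoc on mean ranks
  (studentized-range reference, the standard companion to Friedman).
  The Friedman statistic is computed directly from the rank-sum formula
  with mid-ranks so that fully tied designs return exactly 0 (library
  implementations divide by a tie correction that is 0 there); on
  tie-free data it matches scipy to machine precision, which the tests
  verify.  Incomplete subject blocks are dropped with a warning; fewer
  than 5 complete blocks is an error.

## Synthetic data

The generator emulates the *structure* the analysis assumes, not any
commercial lens or patient:

* Bench TF-MTF curves: Gaussian focal peaks (σ = 0.30 D; 0.45 D for the
  diffractive-EDOF designs, whose two foci merge) at far and at −add on
  the vergence axis, peak bench MTF 0.42 (below the 0.798 diffraction
  limit at 15 cpd); refractive EDOFs are smoothed plateaus.  The packaged
  design classes carry the adds of the six commercial targets
  (trifocals +2.17/+3.25, +1.75/+3.5, +1.66/+3.33 D; EDOFs +1.75, +1.53,
  +1.9 D).
* Subject cohorts: a deterministic template maps each lens's TFVS
  affinely onto [−0.1, 0.8] logMAR (best optics → best acuity), plus a
  per-subject intercept (sd 0.05 logMAR) and independent residual noise
  (sd 0.11 logMAR, the intersubject spread reported for simulator-based
  acuity).  Defaults: 15 subjects per lens, the +1.00 to −4.00 D grid.
  A mandatory seed makes regeneration bit-identical.
* DOF-gain records: baselines uniform on 1.0–2.5 D, gains with planted
  slopes (defaults −0.96 D/D trifocal, −0.57 D/D EDOF), subject sd
  0.15 D, residual sd 0.2 D, six lenses across two sessions.

What passing tests on these data do *not* show: behaviour under real
digitization noise, chromatic effects beyond three-wavelength weighting,
pupil-size dependence, residual accommodation, or any neural contribution
to acuity — the synthetic acuity model is a monotone optical surrogate.

## Problem sizes and determinism

The validation suite runs the full chain on five designs (101-sample
targets, 101 candidate additions), 100 mixed-model replicates at 15
subjects, and 1000 Friedman null replicates — a few seconds each on one
core.  All simulations use explicit seeds; the lens-programming chain
itself is deterministic given a design.

## Known limitations

* The entrance-pupil conversion is an identity by default; users with a
  specific pseudophakic eye model must supply the factor.
* The lag compensation adjusts dwell fractions only; it cannot remove
  transition-bin smear, which grows with τ and dominates beyond ≈ 2 ms.
* The TFVS→logMAR template is a convenience for synthetic cohorts, not a
  validated psychophysical mapping; the package deliberately does not
  predict acuity from optics.
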