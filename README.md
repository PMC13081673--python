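# iolsim

Temporal-multiplexing simulation of multifocal and extended-depth-of-focus
(EDOF) intraocular lenses, and analytics for defocus visual-acuity curves.

## The problem

Presbyopia-correcting intraocular lenses (trifocals, EDOFs) trade contrast
at the far focus for usable vision at intermediate and near distances.  A
temporal-multiplexing visual simulator lets a patient *experience* a
candidate lens before surgery: an optotunable lens cycles its optical power
through a small set of additions within a 20 ms period (50 Hz), so the
time-averaged retinal image mimics the multifocal's simultaneous-vision
optics.  Programming such a simulation from public bench data, validating
it, and comparing the resulting defocus visual-acuity (DFVA) curves across
lens designs is the workflow this package implements, for researchers in
visual optics and for anyone building or evaluating simulated-lens
protocols.

## The model

**From bench MTF to a target optical signature.**  Published through-focus
MTF curves at ν = 15 cycles/degree (3 mm pupil) are normalized by the
diffraction-limited MTF of a circular aperture,
`MTF_dl(s) = (2/π)(arccos s − s√(1−s²))` with `s = ν/ν_cutoff`
(ν_cutoff ≈ 94.3 cpd at 3 mm, 555 nm), averaged over wavelengths with
luminous-efficiency weights (R/G/B = 0.11/0.99/0.15), and smoothed with a
zero-phase Kaiser-window low-pass FIR (passband 0.05 D⁻¹, stopband
0.5 D⁻¹, 0.05 dB ripple, 10 dB attenuation, applied forward–backward).
The result is the estimated through-focus visual Strehl ratio, TFVS(d).

**Temporal coefficients.**  The simulator must find dwell fractions `c_k`
and additions `a_k` (on a 0.05 D grid) such that

    TFVS(d) ≈ Σ_k c_k · K(d + a_k),      c_k ≥ 0,  Σ c_k = 1,

where `K` is the through-focus response of a single focal state — the
rectified, peak-normalized defocused MTF of the pupil at ν.
`TemporalMultiplexModel.fit()` solves this by nonnegative least squares
followed by backward elimination (drop the coefficient whose removal
costs least RMSE, refit, stop when a step would cost more than a
tolerance), returning a `TemporalMultiplexResults` with the profile, the
fitted curve and agreement diagnostics.

**Validation.**  A simulated high-speed focimeter drives a first-order-lag
lens model (τ = 1 ms by default) with the commanded 20 ms staircase, bins
the realised power into effective dwell fractions, and compares the
resulting TFVS against the nominal reconstruction.  An iterative dwell
compensation (the software analogue of tuning the hardware drive signal
against focimeter feedback) counters the lag.

**DFVA analytics.**  logMAR acuity versus vergence (+1.00 to −4.00 D,
0.50 D steps): RMSE-minimizing offset alignment (closed form: mean
difference), zero-lag Pearson correlation and RMSE, depth of focus (total
dioptric measure with logMAR < 0.20), and benefit/degradation versus a
monofocal reference at far (0 D), intermediate (−1.5 D) and near
(−2.5 D).  Cohort statistics: a linear mixed-effects regression of DOF
gain on the monofocal baseline (random subject intercept, REML) and
repeated-measures comparisons across lenses (RM-ANOVA + Bonferroni when
residuals are normal, otherwise Friedman + Tukey–Kramer on ranks).

## Worked example

Program a trifocal-like design (adds +1.75/+3.5 D) from its synthetic
bench curve:

```python
import iolsim

result = iolsim.program_lens_from_design("trifocal_b")
print(result.fit_summary)
```

```
Temporal multiplexing fit
================================================
n target samples                             101
n candidate additions                        101
n states (coefficients)                        5
backward-elimination steps                    42
residual RMSE (VS units)                 0.00045
cross-correlation                        0.99989
mixture amplitude                        0.40823
------------------------------------------------
  addition (D)    dwell fraction    dwell (ms)
         -0.50            0.1369          2.74
          0.35            0.2043          4.09
          1.20            0.2557          5.11
          3.15            0.3246          6.49
          3.60            0.0786          1.57
```

Five dwell states reproduce the estimated TFVS with cross-correlation
0.99989 and residual RMSE 0.00045 visual-Strehl units; the lens spends,
for example, 6.49 ms of every 20 ms cycle at a +3.15 D addition.  The
focimetry validation under 1 ms lens dynamics stays within the hardware
bounds (here RMSE 0.021 VS units, peak shift 0.10 D — the acceptance
bounds are RMSE < 0.05 and shift < 0.2 D):

```python
print(result.focimetry_agreement.to_dict())
# {'cross_correlation': 0.854, 'rmse': 0.0212, 'peak_shift_D': 0.10}
print(result.passed)
# True
```

The same chain is available from the shell:

```bash
iolsim program-lens --design trifocal_b --out out/
iolsim analyze-dfva --dfva-csv cohort.csv --out out/
```

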