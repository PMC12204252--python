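# Methods

## Overview

`ofc_biosig` implements an analysis chain for deriving and transferring an
EEG biomarker of widespread hyperalgesia — heightened pain sensitivity at
body sites anatomically unrelated to the disease site, a hallmark of
centrally amplified (nociplastic) pain. The chain models stimulus-evoked
oscillatory power in the medial orbitofrontal cortex (mOFC) as a function
of pain phenotype, condenses the phenotype-discriminating pattern into a
fixed time-frequency projection mask, and evaluates the resulting scalar
scores for phenotype discrimination and treatment-response prediction in a
second cohort. Because the package ships no recordings, a synthetic-data
generator reproduces the statistical structure of such a study end to end.

## Time-frequency processing

Inputs are ROI-level trial epochs spanning −1 to 1 s around a mechanical
pinprick stimulus. Each trial is decomposed with the multitaper method
(`mne.time_frequency.tfr_array_multitaper`) at integer frequencies
1–45 Hz. The per-frequency sliding-window length is `n_cycles/f` with
`n_cycles = max(f/2, 1)` (a half-second window at and above 2 Hz, one full
cycle at 1 Hz) and time-bandwidth 4.0; both are configurable
(`TaperConfig`).

Power is converted to decibels per cell and the per-frequency mean dB over
the −0.3 to 0 s pre-stimulus window is subtracted per trial, so each
frequency's baseline mean is exactly zero afterwards. Subtracting the
baseline on the log scale (rather than subtracting raw power and then
taking logs) is the standard evoked-TFR convention and keeps the correction
multiplicative in power. Corrected trials are averaged and the 0 to 0.7 s
post-stimulus segment is decimated by nearest-sample selection onto the
analysis grid of T = 27 equispaced time bins (spacing 0.7/26 ≈ 27 ms) and
F = 45 frequency bins. All window and band membership is decided on bin
centers with closed intervals.

## Phenotyping rules

*Hyperalgesia threshold.* Pain-free controls' mean 0–10 ratings of
low-force stimulation at the disease-unaffected site define a cut-off of
mean + 2 sample standard deviations (n−1 denominator). Patients whose mean
rating at that condition is strictly above the cut-off are labeled
widespread hyperalgesia; at or below, localized pain; controls are "no
pain". Equality at the threshold is resolved toward the conservative
(localized) class because the rule's verbal form ("below … localized,
above … widespread") leaves ties unspecified.

*Responder rule.* A treatment responder shows a relative reduction in pain
severity of at least 30% at follow-up ((baseline − followup)/baseline ≥
0.30, inclusive); a zero baseline is rejected as undefined.

*Harmonization.* The pancreatitis frame (no / segmental / widespread
hyperalgesia) maps onto the pooled frame by collapsing no- and segmental-
hyperalgesia patients into the "localized pain" class; only the widespread
label crosses cohorts unchanged.

## The Bayesian functional mixed model

Each subject × condition outcome Y (T × F, baseline-corrected dB) is a 2D
functional response expanded in a tensor product of marginal cubic
B-spline bases — 5 time functions on [0, 0.7] s and 10 frequency functions
on [1, 45] Hz, giving 50 tensor surfaces that form a partition of unity in
each margin. The model is

Y_ic = (x_ic′ γ) · S(u, v) + Z b_i + Z b_ic + ε_ic,

with

* **fixed effects**: one shared rank-1 surface S(u, v) = (B_t u)(B_f v)′,
  u ∈ S⁴, v ∈ S⁹ unit-norm direction vectors, scaled per design column by
  scalar amplitudes γ. The design has one intercept indicator per stimulus
  condition, one group-by-condition indicator per non-reference phenotype
  (localized pain is the reference, so the widespread-vs-localized contrast
  at a condition is a single coefficient), and shared covariates: z-scored
  age and pain intensity, sex as 0/1, and a cohort indicator in pooled
  runs. Rank R > 1 adds further (u_r, v_r, γ_r) components.
* **random effects**: subject and subject-by-condition surfaces expanded in
  the same 50-dimensional tensor basis, coefficients i.i.d. N(0, σ_b²)
  with one variance per family.
* **noise**: i.i.d. Gaussian over grid cells, variance σ².

Priors: uniform-on-the-sphere for u and v; local–global conjugate
shrinkage for amplitudes, γ_{k,r} ~ N(0, τ²λ_k²/φ_r) with λ_k² ~ IG(1, 1),
τ² ~ IG(0.001, 0.001) and a multiplicative-gamma ordered precision φ_r
across rank components (shapes 2 then 3); IG(0.001, 0.001) on
random-effect variances; Jeffreys p(σ²) ∝ 1/σ² on the error variance.

Every full conditional is conjugate, so fitting is plain Gibbs sampling
(default 1500 burn-in + 500 kept draws, seedable and reproducible
bit-for-bit). The direction vectors are updated by parameter expansion:
the unconstrained Gaussian full conditional is drawn, then normalized with
the norm absorbed into γ, which preserves the sphere parameterization
without Metropolis steps. Because all model terms lie in the 50-dim basis
span, the sampler works with the projected data B′y and the basis Gram
matrix; one iteration costs a few 50 × 50 Cholesky factorizations shared
across subjects, so a 40-subject fit takes seconds.

*Sign identifiability.* The likelihood is invariant to (u, v, γ) →
(−u, −v, γ) and (u, γ) → (−u, −γ). Draws are aligned so the basis
surface's mean over the delta/theta cells (1–7 Hz) in the 0.4–0.7 s window
is non-negative; a component with essentially no mass there (|mean| ≤ 1%
of the surface norm) is instead kept aligned with its previous draw, which
keeps signs coherent without distorting informative components.

*Numerical safeguards.* σ² is floored at 10⁻¹⁰ (relevant only for exactly
degenerate data); direction-vector precisions carry a 10⁻⁸ ridge so the
flat-prior conditional is proper when the current amplitudes are all zero;
the initial σ² is max(var(Y), floor) so all-zero data stays at the
degenerate fixed point. Missing subject × condition cells are dropped from
the likelihood; no imputation.

*Rank selection.* The model is fitted at R_max with the ordered shrinkage
prior; a component is "active" if any design column's 95% amplitude
interval excludes zero, and the selected rank is the largest active
component index (1 if none, flagged). In simulations this recovers rank 1
and rank 2 truths and returns 1 on pure noise.

*Contrast scale.* Posterior contrast summaries default to the "surface"
scale: each rank's amplitude is multiplied per draw by the Frobenius norm
of that rank's basis surface, so a contrast is expressed as the magnitude
of a unit-norm T × F effect surface. This makes amplitudes comparable
across draws, to generative truths, and across refits; the raw basis-scale
amplitudes remain available.

## Biosignature and projection scores

The biomarker is deliberately not learned: it is a fixed ±1 mask with +1 on
1–7 Hz (delta/theta) cells and −1 on 8–12 Hz (alpha) cells inside the
0.4–0.7 s post-stimulus window (84 and 60 cells on the default grid), zero
elsewhere. A TFR's projection score is the plain weighted sum of dB power
(no cell-count normalization, keeping the ±1 weights literal). A subject's
score per hemisphere averages the three conditions that probe the
phenotype (affected-site high, unaffected-site high, unaffected-site low
intensity) — the arithmetic mean rather than the sum, so adding a
condition leaves scores on one scale — and both per-hemisphere scores and
their average are emitted; downstream prediction uses the average by
default.

## Transfer and prediction

Scores from a new cohort (never used to refit the mask) are compared
across the three phenotype groups with a classical one-way ANOVA followed
by Tukey HSD post-hoc tests with Tukey–Kramer standard errors (group sizes
8/4/6 in the emulated pancreatitis cohort are unequal). Treatment response
is modeled by OLS of 3-month pain change on score, binary widespread
phenotype, and their interaction, compared against widespread-only and
three-level-phenotype-only models on R², adjusted R² and leave-one-out
cross-validated classification. In each LOOCV fold the model is refit
without the held-out subject; AUC ranks the negated predicted pain change
against observed responder labels (more negative = more responder-like,
midranks for ties), and accuracy/sensitivity/specificity threshold the
predicted relative reduction at the same 30% used for observed responders
— the analysis's own convention, since the verbal description of the
original procedure does not pin one down.

## The synthetic-data generator

Each subject × ROI × condition TFR is built as amplitude(group, condition)
· true_surface + (covariate effects) · true_surface + subject surface +
subject-by-condition surface + i.i.d. cell noise.

* **True surface** (unit Frobenius norm): a Gaussian time profile centered
  at 0.55 s (SD 0.08 s) times a frequency profile of a positive bump at
  4 Hz minus a bump at 10 Hz (SD 1.5 Hz), least-squares projected into the
  5 × 10 spline span. Sharing one time profile makes the truth exactly
  rank-1 and living in the spline span keeps recovery and coverage tests
  well-posed; the shape mimics the elevated-delta/theta, suppressed-alpha
  pattern without asserting its exact form.
* **Amplitudes**: all groups share a base evoked response (2 dB-units at
  low, 5 at high intensity); widespread subjects add 9 at affected-high,
  4 at unaffected-high and 2 at unaffected-low. The key
  widespread − localized difference of 9 at the affected-site high
  condition matches the magnitude reported for the real cLBP cohort; the
  spillover values are package choices with no reported counterpart.
* **Random structure**: subject and subject-by-condition surfaces are
  spline-coefficient draws (SDs 0.5 each) through the same tensor basis —
  inside the fitted model family — plus cell noise with SD 1.0 dB. In cell
  space the random-surface variance is (σ_s² + σ_sc²)·‖basis row‖², which
  the tests verify against the empirical variance in closed form.
* **Covariates**: age ~ U[25, 70], sex ~ Bernoulli(0.5), pain intensity ~
  group-specific truncated normals on [0, 10] with means/SDs from the
  reference cohort tables; their surface effects (0.5, 0.3, 0.8 per
  standardized unit) are applied through fixed centering constants so the
  generative model does not depend on the realized sample.
* **Ratings**: truncated normals on [0, 10] per group × condition
  (`scipy.stats.truncnorm`), with widespread subjects rating the
  unaffected-site low-force stimulus well above the control range.
* **Outcomes**: pain change = −1.2 + 0.06·(score − 40) + 1.0·widespread −
  0.06·(score − 40)·widespread + N(0, 0.8²), added to a truncated-normal
  baseline severity and clipped to [0, 10]. The centering constant 40 is
  the typical non-widespread score under default settings; the interaction
  cancels the score slope for widespread subjects, reproducing the
  qualitative pattern that lower scores predict improvement only among
  non-widespread patients and widespread patients rarely respond.

Default cohort compositions mirror the reference studies: 25/30/12
(controls/localized/widespread) in the cLBP frame and 6/4/8
(no/segmental/widespread hyperalgesia) in the CP frame; a 40-subject
12/16/12 configuration is provided for recovery studies.

What the generator does **not** emulate: raw multichannel EEG, electrode
geometry or source leakage; non-Gaussian or temporally correlated noise;
spatial correlation between ROIs; the pancreatitis QST battery itself (CP
phenotype labels are generated directly). Passing tests therefore
demonstrate the correctness and calibration of the analysis under its own
assumptions, not robustness to the artifacts of real recordings.

## Problem sizes and reproducibility

The shipped test suite and the acceptance script use the cohort sizes
above with 1500 + 500 MCMC iterations per fit, 10 replicate fits for the
recovery/coverage study and 200 simulated cohorts for the type-I-error
study — sizes chosen so a full run of everything completes in a few
minutes on one core while keeping Monte-Carlo error well inside the
asserted bands. Every random draw flows from explicit seeds
(`numpy.random.default_rng`); the pipeline derives stage-specific streams
by hashing a single global seed with the stage name, so toggling one stage
never perturbs another's randomness, and reruns are bit-identical (exact
stages) or draw-identical (MCMC).

## Known limitations

* Real-data headline results from the studies this design emulates (e.g.
  a group contrast of ~9 with its credible interval, transfer ANOVA
  p-values, R²/AUC of the prediction models) depend on the actual
  recordings and cannot be reproduced synthetically; the package
  reproduces the *procedures* and validates them by parameter recovery,
  calibration and oracle equivalence instead.
* The rank-selection rule (interval-covers-zero truncation under ordered
  shrinkage) and the shrinkage hyperparameters are concrete choices for a
  procedure whose original description is underdetermined; both are
  configurable.
* LOOCV metrics on 18-subject cohorts are highly variable; the acceptance
  script reports them for one seeded cohort, not as stable estimates.
* The Gibbs sampler mixes slowly if the error variance is driven to its
  floor with random effects enabled (fixed effects and random surfaces
  then trade off through a near-degenerate likelihood); noiseless
  validation fits disable the random effects, as their tests do.
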