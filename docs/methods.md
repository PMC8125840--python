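# Methods

`stsfrail` implements a digital-biomarker pipeline for physical frailty
built on the five-times-sit-to-stand test (5×STS): a subject rises from and
returns to a chair five times as fast as possible while wearing inertial
sensors on the trunk, thighs and shanks.  The pipeline turns the recorded
segment kinematics into 17 sensor-derived features, screens them by group
statistics, ranks them with a bootstrapped recursive-feature-elimination
(RFE) procedure over logistic models, selects a minimal phenotype-covering
subset, and evaluates a logistic frailty classifier.  Because no public
cohort exists for this protocol, the package ships a synthetic-data
generator with known ground truth; every quantitative claim in the test
suite is made against that generator, closed-form mathematics, or
brute-force oracles.

## Feature model

A trial is represented by sagittal pitch angles (radians, measured from
vertical) of the trunk, thigh and shank plus the vertical trunk
displacement (m), sampled at 100 Hz.  Joint angles are sagittal-plane
differences: hip = trunk − thigh, knee = thigh − shank.  Eight primary
signals are formed per trial:

* hip/knee joint angle (rad),
* hip/knee angular velocity (rad/s),
* hip/knee angular power `P = I·α·ω = τ·ω` (W),
* vertical velocity (m/s) and vertical power `P = m·v·a` (W).

For each of the five stand–sit cycles the *range* (max − min inside the
cycle interval) of each signal is computed; the feature set is the mean and
the coefficient of variation (CV = sample SD / mean, `ddof = 1` over the
five cycles) of each per-cycle range, plus the sensor-based 5×STS duration
— 17 features in all.  Means of velocity features and the duration proxy
*slowness*, means of angle/power features proxy *weakness*, and all CVs
proxy *exhaustion*.

Numerical choices:

* **Smoothing.** All channels are smoothed with a zero-phase
  Savitzky–Golay filter (0.25 s window, polyorder 3; ≈5 Hz equivalent
  cutoff at 100 Hz, the standard band for sit-to-stand kinematics).  A
  finite symmetric FIR kernel was chosen over an IIR Butterworth +
  `filtfilt` deliberately: its support is 0.25 s, shorter than the seated
  pause between cycles, so identical repeated cycles produce bit-identical
  smoothed output and the cycle-to-cycle CVs of a jitter-free trial are
  *exactly* zero rather than zero up to IIR state leakage (~1e−4
  relative).
* **Differentiation.** Central differences on the smoothed signal
  (one-sided at the endpoints); exact for linear trends.  Velocities are
  first derivatives of smoothed angles/displacement; accelerations are
  smoothed first derivatives of the velocities.
* **Moments of inertia.** `I = m_seg · r_gyr²` with segment mass and
  sagittal radius of gyration from the adjusted Zatsiorsky–Seluyanov
  (de Leva) body-segment parameter table (trunk 43.46 % of body mass,
  thigh 14.16 %, shank 4.33 %; radii of gyration as fractions of segment
  length, segment lengths as fractions of stature).  The trunk segment
  rotates about the hip and the shank about the knee.  These are
  implementation constants, not fitted quantities.
* **Scaled vertical power.** The dimensionless form divides by
  `m·g²·h` (the literal printed convention); the conventional dynamic
  scaling `m·g·√(g·h)` is available via `convention="dynamic"`.  No intent
  is guessed between the two; the default follows the printed formula.
* **CV degeneracy.** |mean| < 1e−9 in feature units makes a CV undefined
  (NaN) rather than infinite; identical per-cycle ranges short-circuit to
  an exact 0 SD to avoid an O(ulp) mean-rounding residue.

## Cycle segmentation

Thigh pitch is high when seated (≈1.40 rad) and low when standing
(≈0.10 rad).  Candidate stands are runs of the smoothed thigh pitch below
the 50 % point of its global amplitude, validated by hysteresis: a run must
reach below the 40 % level, and consecutive runs must be separated by a
return above the 60 % level (otherwise they are merged as noise dips).
Because a symmetric stand–sit transition spends its middle half between the
half-amplitude crossings, each cycle's full extent is estimated by
extending the crossing pair symmetrically by half its width; crossings are
located with sub-sample precision by linear interpolation.  A trial is
valid only if exactly five cycles are found; otherwise an
`InvalidTrialError` carrying the detected count is raised and the subject
is excluded (with a logged reason) rather than silently dropped.  The
sensor-based duration is the first cycle onset to the last return-to-sit.

Known limitation: the hysteresis bands are derived from the *global*
amplitude, so trials with very large cycle-to-cycle amplitude variability
(relative SD ≳ 0.15) can fail validation — such trials are reported
invalid, which is the intended behaviour for a screening pipeline, and the
band levels are not tuned per trial.

## Statistical screening

Each feature is compared between the robust (status 0) and pre-frail/frail
(status 1) groups.  Normality is assessed *per group* with Shapiro–Wilk;
only when both groups pass at α is the classical equal-variance one-way
ANOVA used (for two groups, F = t²), otherwise a two-sided Mann–Whitney U
test (exact when the smaller group has ≤ 8 subjects and no ties are
present, normal approximation with tie correction otherwise).  α = 0.05
throughout and no multiplicity correction by default, matching the
reference analysis; Benjamini–Hochberg is available behind
`correction="bh"`.  Features with p < α, in canonical order, form the RFE
candidate set.

## Bootstrapped RFE and the optimal-subset rule

The cohort is resampled into B = 2000 bootstrap pairs (training drawn with
replacement at full size, stratified within class; validation =
out-of-bag, redrawn until both classes are present — the expected OOB
fraction is (1 − 1/n)ⁿ ≈ 0.366 at n = 102).  Each pair has its own
counter-derived random substream, so B can grow without reshuffling
earlier pairs, and the whole procedure is bit-reproducible from one seed.

Per elimination loop, one unpenalised maximum-likelihood logistic model is
fitted per remaining candidate, *excluding* that candidate, on every
training set, and scored by the rank-based AUC on the paired validation
set; per-candidate AUCs are averaged over B.  The feature whose exclusion
model scores *highest* — i.e. the feature the model misses least — is
eliminated; ties break toward canonical feature order.  The literal
opposite reading (remove the lowest-AUC exclusion model) is available
behind `literal_elimination=True` but discards the most informative
feature first and is not the default.  Loops repeat while ≥ 2 features
remain, so k starting features cost `B·Σ_{j=2..k} j` fits — exactly 70,000
for k = 8, B = 2000 — and the ranking is the reverse elimination order.
Per-k subset AUCs (the model on the top-k ranked features) are computed on
the same splits for comparability.

The optimal subset is the smallest top-k prefix that (a) covers all three
phenotypes — slowness, weakness, exhaustion — and (b) has subset AUC >
0.80.  If no prefix qualifies, an explicit inadmissible result is
returned.

The inner logistic solve is a hand-written Newton–Raphson on standardized
columns (iteration-capped, logits clipped at ±35, tiny ridge on the
Hessian solve; standard errors from the inverse observed information
mapped back to the raw scale).  This keeps the ~10⁵ fits of a full run
inside seconds-to-a-minute; the fit is validated against the statsmodels
MLE (coefficients and standard errors) in the test suite.  Quasi-separated
fits (saturated linear predictors) are flagged `converged=False`; their
scores still order subjects, so validation AUCs remain usable.

## Model evaluation

Per bootstrap pair the model is refitted on the training resample and
scored out-of-bag.  AUC uses the rank (Mann–Whitney) formulation with ties
half-weighted; sensitivity, specificity and accuracy
`(TP+TN)/(TP+TN+FP+FN)` use a posterior-probability threshold of 0.5 by
default (a Youden-optimal-on-training threshold is available).  Metrics
are reported in percent with a 95 % CI over the B per-iteration values —
percentile (2.5/97.5) by default, with a mean ± 1.96·SD/√B
(standard-error-of-the-mean) variant labelled in the report.

The published three-feature scorer is shipped as a fixed-coefficient
model: `logit p = 2.722 − 0.022·ph₁ + 0.243·ph₂ + 0.055·ph₃` with ph₁ =
mean hip angular velocity range, ph₂ = mean vertical power range, ph₃ = CV
of vertical power range.  The source prints no units for ph₁–ph₃; the
scorer documents its assumption (deg/s, W, percent) and exposes
multiplicative converters rather than guessing.

## Synthetic cohorts

Two generation paths share one `CohortSpec` (default 42 robust + 60
pre-frail/frail, 100 Hz, one master seed; per-subject counter streams so
growing a group never perturbs existing subjects):

* **Waveform path.** Per cycle of duration d, the thigh pitch moves
  seated → standing → seated along a raised cosine — algebraically a pure
  cosine over the cycle — the trunk lean and shank modulation are
  raised-cosine pulses on the same phase, and the vertical displacement
  rises by a cubic smoothstep and mirrors back.  All waveforms have
  closed-form ranges (`closed_form_ranges`): angle range A, velocity range
  2πA/d, angular-power range 2IA²π³/d³, vertical-velocity range 6r/d,
  vertical-power range 32√3·m·r²/d³.  Cycle extents are realized on the
  sample grid so identical parameters give bit-identical cycles.
  Per-cycle durations and amplitudes are jittered with relative SD
  `cycle_cv`; white noise (SD 0.01 rad by default) is added to the angle
  channels.  Group structure enters through standardized shifts on
  generator parameters (frail default: cycle duration +1.2 SD, vertical
  rise −0.6 SD, cycle CV +0.8 SD), so feature-level effects *emerge*
  through extraction: longer duration, slower angular velocities, lower
  powers, higher CVs.  Demographics follow the published group
  distributions (robust 66.8 ± 12.2 kg, 1.62 ± 0.07 m; frail 78.6 ± 20.0
  kg, 1.65 ± 0.11 m).  Seated/standing pitch constants (thigh 1.40 → 0.10
  rad, shank 0.35 rad, trunk lean pulse 0.35 rad, vertical rise 0.45 m,
  cycle 1.2 s + 0.3 s pause) are fixtures producing physiological
  magnitudes, not calibrated claims — the reference study publishes no
  numeric kinematics.
* **Table path.** The 17 features are drawn directly from independent
  normals with plausible baselines; frail means are shifted by
  `feature_effects[name]·SD`.  The default plants the eight
  reference-significant analogues with the reported signs (d between 0.6
  and 1.0); zero-effect and custom planted maps support null-calibration
  and recovery studies.  Because features are independent and Gaussian
  here, this path is the right substrate for statistical unit tests but
  does not emulate the correlation structure of real biomechanics — a
  deliberate limitation.

What passing tests show, and don't: recovery/calibration results certify
the *machinery* (segmentation, extraction arithmetic, routing, RFE
combinatorics, metric estimators) under known generative conditions.  They
do not certify that real 5×STS data would reproduce any published cohort
value; the real recordings are not publicly deposited.

Numerical differentiation note: the raised-cosine/smoothstep family has a
step in acceleration at the cycle boundaries, so the twice-differentiated
power ranges carry a few percent of ringing bias (≈5 % angular, ≈9 %
vertical at the defaults); angle, velocity and duration recovery are
well inside 2 % / 1 sample.  The package's own recovery tests hold powers
to 12 % and the tighter quantities to their closed forms.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` size their simulations to run
comfortably on a single CPU: the exact fit-count identity is executed at
the full reference configuration (8 features, B = 2000, n = 102 →
70,000 fits); planted-recovery and Gaussian-limit checks use B = 200 over
10–20 seeded cohorts; null calibration uses 1000 replicate tables; oracle
equivalence uses exhaustive enumeration at ≤ 20 subjects.
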