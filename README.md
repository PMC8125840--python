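# stsfrail

Digital biomarkers of physical frailty from the sensor-instrumented
five-times-sit-to-stand test (5×STS).

Conventional frailty screening (the Fried phenotype: weight loss, weakness,
slowness, exhaustion, low activity) is resource intensive and hard to
administer remotely.  `stsfrail` implements the alternative: a subject
wearing inertial sensors on trunk, thighs and shanks stands up and sits
down five times as fast as possible; the package extracts **17
sensor-derived features** from the segment kinematics — the 5×STS duration
plus the mean and the cycle-to-cycle coefficient of variation
(CV = SD/mean over the five cycles) of eight primary per-cycle ranges
(hip/knee angle, hip/knee angular velocity, hip/knee angular power
`P = I·α·ω`, vertical velocity, vertical power `P = m·v·a`) — and
identifies a minimal feature subset that classifies pre-frail/frail vs
robust status while covering the slowness, weakness and exhaustion
phenotypes.

The selection procedure is a **bootstrapped recursive feature
elimination**: the cohort is split into B = 2000 bootstrap
training/out-of-bag validation pairs; per elimination loop one logistic
model is fitted per remaining candidate *excluding* that candidate, scored
by validation AUC and averaged over the B pairs; the feature whose
exclusion model scores highest (i.e. the least informative) is eliminated
until one remains (`B·Σ_{j=2..k} j` fits — exactly 70,000 for 8 candidates).
The optimal subset is the smallest top-k prefix of the resulting ranking
that covers all three phenotypes with subset AUC > 0.80.  A published
fixed-coefficient three-feature scorer,
`logit p = 2.722 − 0.022·ph₁ + 0.243·ph₂ + 0.055·ph₃`
(ph₁ = mean hip angular velocity range, ph₂ = mean vertical power range,
ph₃ = CV of vertical power range), is included for direct scoring.

Since no public cohort exists for this protocol, the package ships a
seeded synthetic 5×STS generator (waveform-level and feature-table-level)
with known ground truth; see `docs/methods.md` for the model, defaults and
what the synthetic results do and do not demonstrate.

## Worked example

```python
import stsfrail as sf

# synthetic cohort (42 robust / 60 pre-frail-frail) with a standardized
# shift of 1.5 SD planted on the three-feature "optimal trio"
spec = sf.CohortSpec(seed=42, feature_effects=sf.planted_effects(
    ["mean_hip_angular_velocity_range", "mean_vertical_power_range",
     "cv_vertical_power_range"], 1.5))
table = sf.generate_feature_table(spec)

candidates, _ = sf.significant_features(table, alpha=0.05)
cfg = sf.SelectionConfig(B=200, seed=42)
splits = sf.make_bootstrap_pairs(table["status"].to_numpy(), cfg)
trace, ranking = sf.rfe_rank(table, candidates, cfg, splits=splits)
result = sf.select_optimal(ranking, cfg)
perf = sf.bootstrap_performance(result.selected, table, splits)
```

This prints (via the obvious `print` calls):

```
significant features: ['mean_hip_angular_velocity_range', 'cv_knee_angular_velocity_range',
                       'mean_vertical_power_range', 'cv_vertical_power_range']
leave-one-out fits executed: 1800
ranking: ['mean_hip_angular_velocity_range', 'cv_vertical_power_range',
          'mean_vertical_power_range', 'cv_knee_angular_velocity_range']
selected: ['mean_hip_angular_velocity_range', 'cv_vertical_power_range',
           'mean_vertical_power_range'] (k=3, AUC=0.961)
AUC 96.09% (95% CI 91.83-99.47)
sensitivity 90.54%  specificity 81.32%  accuracy 86.65%
```

The screen kept the three planted features plus one false positive
(expected at α = 0.05); the RFE ranked the planted trio first and the
false positive last; the smallest prefix covering slowness + weakness +
exhaustion with AUC > 0.80 is exactly the planted trio, whose refitted
model classifies the out-of-bag subjects with the performance shown
(mean and percentile 95 % CI over the 200 validation sets, in percent).

Scoring a single subject with the published model
(`ph₁` in deg/s, `ph₂` in W, `ph₃` in %):

```python
>>> sf.published_score(55.3, 4.2, 12.5)
0.9613
```

A command-line interface mirrors the stages:

```bash
stsfrail simulate --seed 42 --out cohort.csv
stsfrail select cohort.csv -b 200 --seed 42 --out selection.json
stsfrail score 55.3 4.2 12.5
stsfrail run config.yaml         # full pipeline from a YAML config
```

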