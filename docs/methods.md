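# Methods note

## Statistical model

For subject *i*, acquisition-protocol group *g*, and region *r*, the
pre-event scans are modeled as

&nbsp;&nbsp;&nbsp;&nbsp;V = β₀ + β₁ · age + ε,&nbsp;&nbsp;ε ~ (0, σ²) i.i.d.,

fitted by ordinary least squares on the `n_pre ≥ 3` pre-event scans of the
group. The residual standard deviation is `s = sqrt(RSS / (n_pre − 2))`
(n_pre − 2 degrees of freedom). Every scan in the group — pre and post —
is standardized against this fit:

&nbsp;&nbsp;&nbsp;&nbsp;z = (V − (β₀ + β₁ · age)) / s.

Pre-event raw residuals sum to zero exactly (OLS normal equations); z is
invariant under volume rescaling, age shifts, and adding any affine trend
in age (asserted in the invariance suite).

Per region, post-event z values pooled across subjects are compared with
pre-event z values by a two-sided two-sample *t* test. Variants:

- **welch** (default): unequal-variance statistic with Welch–Satterthwaite
  degrees of freedom. Undefined against a single post observation; when a
  region ends up with exactly one pooled post residual the pooled statistic
  is substituted automatically (the only defined two-sample test there).
- **pooled**: classic pooled-variance statistic, defined down to one post
  observation.

Residual pooling:

- **all_scans**: every scan's residual is one observation; repeated post
  scans of one subject enter individually (and are correlated, since they
  share the subject's fitted line and s).
- **per_subject_mean**: each subject's post residuals are first averaged,
  so every subject contributes one post observation; pre residuals stay
  individual (they already average to zero within each fit).

Benjamini–Hochberg false-discovery-rate adjustment (optional) runs across
the regional tests only; the global gray-matter measure is a distinct
hypothesis and is excluded from the family.

## Assumptions

- Within a subject and protocol group, pre-event volume is linear in age
  over the observation window with homoscedastic noise.
- The event does not change measurement noise, only (possibly) the level
  and/or slope of the trajectory.
- Scans are comparable only within protocol groups matched on field
  strength, repetition time, and inversion time; between-protocol level
  differences are absorbed by fitting each group separately.
- Subjects are independent; regions are tested marginally.

## Eligibility

A subject contributes one analysis group per protocol key under which they
have at least `min_pre = 3` pre-event scans **and** at least one post-event
scan on the same key. Subjects may contribute multiple groups (one per
key). Optional filters: `require_stable` (drop subjects flagged with
unstable disease course, default on in the pipeline), and subgroup
selection (`untreated_unvaccinated` / `treated_or_vaccinated`). Every
exclusion is counted and reported (`EligibilityReport`), never silent.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `min_pre` | 3 | scans | minimum for a 2-parameter fit with ≥ 1 residual dof |
| protocol key rounding | TR/TI to 1 ms, field to 0.1 T | — | absorbs float formatting jitter without merging distinct protocols |
| test `variant` | welch | — | robust to unequal pre/post residual variance |
| `pooling` | all_scans (inference), per_subject_mean (evaluation) | — | per-subject-mean removes within-subject correlation of repeated post scans |
| `alpha` | 0.05 | — | conventional |
| BH family | regional tests only | — | the global measure is a separate hypothesis |

Simulator defaults (`SimConfig`): 14 subjects; pre-event scan count uniform
on {3,…,13}; post-event count on {1,2,3} with weights (0.65, 0.30, 0.05)
(mean 1.4); event age uniform on [17, 64] years; pre-event inter-scan gaps
uniform on [6, 18] months; first post-event gap uniform on [0.4, 10]
months, later gaps [1, 8] months; regions with baseline volume mean/SD,
atrophy slope mean/SD (mm³/year, negative mean) and per-scan noise SD in
mm³; protocol set of (field, TR, TI) keys with additive per-key offsets
specified as a fraction of the region's baseline mean (regional volumes
span three orders of magnitude, so a single absolute offset cannot serve
all regions); probability of a subject switching protocol mid-series
(default 0 — subjects keep one scanner by default); event effect as a
proportional step loss δ ∈ [0, 1) in affected regions (multiplicative,
because volumes span orders of magnitude; an additive mode exists for unit
tests) plus an optional post-event slope change in mm³/year. Realistic
magnitudes for noise and protocol offsets are not identifiable from
summary statistics; the defaults are order-of-magnitude choices to be
replaced by users with real data.

Generative model per scan:
`V = (B + β·age + offset_key) · (1 − δ·I[post, affected]) +
slope_change·(age − event)·I[post, affected] + ε`, `ε ~ N(0, noise_sd²)`.

## Numerical choices

- **Degenerate-SD snap**: a residual SD below 1e-9 of the value scale is
  snapped to 0, so exactly collinear pre points give s = 0 rather than
  float-rounding garbage (z = tiny/tiny). With s = 0, raw residuals below
  1e-8 of scale count as zero and give z = 0 (the noise-free case); any
  larger raw residual raises a degenerate-standardization error rather
  than producing an infinite z.
- **Zero-variance test samples**: both samples constant and equal gives
  t = 0, p = 1; unequal constants give an infinite t and p = 0.
- Seeding uses a hierarchical `numpy.random.SeedSequence` (master →
  subject → schedule/region streams), so adding a region to a config does
  not perturb the draws of existing regions, and identical config + seed
  reproduce byte-identical fixture files.
- Monte-Carlo comparisons across the effect grid reuse the same cohort
  seeds at every effect size (common random numbers), so power
  monotonicity is not washed out by simulation noise. Replicates with
  degenerate fits are excluded and counted; more than 1 % of them fails
  the run loudly.
- Figures are written as deterministic SVG (fixed hash salt, no embedded
  timestamps) so outputs can be diffed byte-for-byte.

## Operating characteristics and known limitations

- **Conservatism at shallow baselines.** With n_pre as small as 3, s is
  estimated with a single degree of freedom, so z = raw/s is (up to a
  leverage factor) t-distributed with n_pre − 2 dof — a heteroscedastic,
  heavy-tailed scale mixture across subjects, not N(0, 1). A two-sample
  *t* test on such observations rejects less often than the nominal level
  at the default cohort depth (3–13 pre scans, 14 subjects). This is
  measured, not assumed: the calibration acceptance test
  (`tests/test_acceptance.py::TestCalibration`, 5 000 null replicates) and
  the `type1_error_per_subject_mean` entry of `scripts/acceptance.py`
  quantify the deficit. As pre-scan counts grow, s → σ and leverage → 1,
  so z → N(0, 1) and calibration is recovered asymptotically. Practical
  consequence: reported p-values are conservative — a significant regional
  finding understates, not overstates, the evidence.
- **All-scans pooling is mildly anticonservative** because repeated post
  scans of one subject share a fitted line and are positively correlated;
  the deviation is measured and reported (`type1_error_all_scans` in the
  acceptance script) rather than corrected.
- **The vanishing-noise power limit depends on the variant.** As
  noise → 0 with δ > 0, every post z diverges like 1/noise, so the Welch
  statistic converges to the scale-free *t* of the inverse-residual-SD
  pattern across subjects — a heavy-tailed, all-negative sample in which
  one subject with a near-zero estimated s can dominate both the mean and
  the variance, capping |t| near 1; the Welch rejection rate therefore
  plateaus strictly below 1. The pooled statistic borrows the O(1)
  pre-sample variance, and any all-same-sign post sample of size n has
  |mean|/sd ≥ 1/√(n−1), which forces |t| above the critical value: its
  limit is 1. Both limits are measured by the
  `low_noise_rejection_rate_*` entries of the acceptance script.
- **Simulator scope.** Regions are statistically independent, and the
  global cortical measure is simulated as its own measure rather than the
  sum of the parcels; spatially correlated atrophy and
  global-from-regional aggregation consistency are out of scope.
  Trajectories are exactly linear — the simulator cannot probe robustness
  to nonlinear aging. Scan schedules are independent of disease course
  (no informative observation times).
- δ̂, the recovered effect size, is the mean of −raw/predicted over
  post-event scans; it is a descriptive summary, unbiased under the
  multiplicative-step generative model (checked at δ = 0.02 in the
  acceptance suite), not a general estimator under slope changes.
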