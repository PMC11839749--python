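# Methods

## The quantity being estimated

`motoriiv` quantifies **intraindividual variability (IIV) in motor
performance** — "motor inconsistency" — from repeated rapid goal-directed
isometric contractions. Each trial is a single force pulse aimed at a
force-time target (10 N peak in 180 ms by default). A trial is summarized
by its **endpoint**: peak force and time-to-peak are expressed as
percentages of their targets and combined as the hypotenuse,

```
peak%     = 100 · peak_force / target_force
time%     = 100 · time_to_peak / target_time
endpoint% = sqrt(peak%² + time%²)
```

An exactly on-target trial has endpoint 100·√2 ≈ 141.42 %. The endpoint is
unitless, so force and timing errors contribute on a common scale.

IIV is *not* the raw SD of endpoints. Raw trial-to-trial variability is
confounded by systematic effects — practice improvement across trials and
mean-level differences between groups. Following the residual-purification
("ISD") approach from the cognitive-aging literature, one pooled OLS
regression is fit over all participant-trials,

```
endpoint ~ 1 + trial_index + group_indicator
```

with trial index entered as a continuous covariate (absorbing a common
linear practice trend) and a group indicator (absorbing mean-level group
differences). Residuals are standardized against the whole-sample residual
SD (z scores), converted to T-scores (T = 50 + 10·z), and each
participant's IIV is the **sample SD of their trial T-scores**. Pooled
T-scores have mean 50 and SD 10 by construction, which makes IIV values
comparable across tasks and cohorts.

### Assumptions of the purification model

- The practice effect is linear in trial index and shared within the
  sample; any common linear drift is removed exactly (a tested invariant).
- Group differences enter as mean shifts only; adding a constant to one
  group's endpoints leaves every IIV unchanged (tested invariant).
- Residuals are standardized once, over the whole sample, not per trial or
  per participant. Consequently a participant's IIV measures their
  within-person spread *relative to the cohort's total residual spread*
  (between-person offsets included); it is a relative, not absolute, scale.
- Sample SDs (n−1) are used throughout, matching common statistical
  software defaults for reported SDs.

## Outlier handling

Endpoint values beyond the group mean ± 3 SD are replaced by the boundary
value and flagged (winsorization), with the mean and SD computed **once on
the raw pooled participant-trials per group**, not iterated after
replacement. The rule is symmetric even though low-side outliers are rare
in practice (a rapid pulse cannot undershoot both force and time by much
without failing onset detection first).

## Feature extraction

Contraction onset is the earliest sample exceeding
`baseline_mean + k·baseline_SD` (baseline = first 100 ms; k = 3) that stays
above threshold for ≥ 25 ms; when the baseline window has zero variance the
threshold falls back to a fixed 0.2 N above baseline mean. Peak force is
the global maximum at or after onset (earliest sample on exact ties);
time-to-peak is peak time minus onset. A 4th-order zero-lag Butterworth
low-pass (20 Hz default cutoff) is available behind a flag and **off by
default** — the onset criterion and the optional filter are documented
package defaults chosen from the force-onset literature, since rapid-pulse
protocols rarely publish them.

Two error sources are worth knowing about. The maximum of noisy samples is
upward-biased by roughly `noise_SD · sqrt(2 ln m)` where m is the number of
samples in the pulse's flat top; low-passing before extraction removes most
of this bias (the test suite bounds the filtered peak error by the sensor
noise SD). Conversely, filtering smears the contraction start backwards and
biases onset early, so time-to-peak accuracy is asserted on the unfiltered
trace (< 5 ms mean absolute error at the default noise level).

## Statistical battery

- **Group comparisons**: two-sample t from group summaries (signed as
  reference group minus stroke group), with pooled or Welch variants.
  The default gating runs Levene's test (mean-centered) at α = 0.05 and
  uses Welch when variance equality is rejected; both variants are
  reachable by explicit override, since published reports often do not say
  which was used per row.
- **Cohen's d** = |mean difference| / pooled SD.
- **Group × Sex ANOVA**: two-way fixed-effects on IIV with **Type III sums
  of squares and sum-to-zero coding** (the design is unbalanced, 66 vs 32),
  implemented by model comparison (SSE increase when an effect's column is
  dropped from the full interaction model) and cross-checked against
  statsmodels' `anova_lm(typ=3)` in the test suite. Partial η² =
  SS_effect / (SS_effect + SS_error).
- **Prediction models**: OLS of stroke-group IIV on (a) the four
  domain-specific cognitive scores, (b) the four global clinical measures.
  Standardized coefficients β = b·s_x/s_y; listwise deletion of incomplete
  cases with a logged count; rank-deficient designs are rejected naming the
  collinear columns.
- **Multiplicity**: Benjamini–Hochberg step-up FDR across the comparison
  table.

## The synthetic cohort generator

No raw data accompany this kind of study, so the generator produces
cohorts with the statistical structure the analysis assumes. It emulates:

- the task geometry: 30 trials/participant, 10 N / 180 ms target, 1000 Hz
  sampling over a 3 s response window;
- **pulse shape**: a truncated Gaussian profile (zero before contraction
  start, single clear peak), half-width-at-half-maximum =
  `pulse_width_factor × time-to-peak` (default 0.5). The truncation leaves
  a small (≈ 6 % of peak) step at contraction start, which makes onset
  analytically identifiable and the template invertible for oracle tests;
- participant-level mean offsets (between-person SD 1.3 N / 23 ms) and a
  mild group aiming bias (stroke 0.97× force, 1.08× time);
- group-dependent trial-to-trial noise — stroke (1.0 N, 17.5 ms) vs
  healthy (0.55 N, 10 ms) — scaled per participant by a **log-uniform
  multiplier on [0.5, 2]**, a 4× latent inconsistency range whose export
  enables recovery testing. These SDs were set by first-order error
  propagation so the emergent group IIV means land near the published
  6.61 / 3.74 T-score-SD values and their ≈1.8× ratio;
- a common linear practice drift (−0.3 ms/trial toward faster pulses);
- outlier trials: with probability 0.02 a trial's noise SD is inflated 3×.
  Because the ±3 SD bounds are computed on the pooled group distribution
  (which includes between-person spread), only a fraction of inflated
  trials actually exceed them; the realized imputation percentage is in the
  low single percents rather than equal to the outlier rate;
- covariates drawn at the published group means/SDs, with cognitive and
  clinical scores linked to the latent noise level through a single
  loading (default 0.5) scaled by fixed signs — worse executive function,
  slower processing and greater disability track higher inconsistency;
  education and global cognition track lower. mRS is drawn only for the
  stroke group and discretized to 0–5. Missingness is explicit NaN/empty,
  never silent zeros.

What the generator does **not** emulate: EMG or kinematics, visual
feedback phases, bilateral-limb data, false starts or no-response trials,
non-Gaussian trial noise, nonlinear practice curves, and any dependence of
covariates on age or lesion characteristics. Passing recovery tests
therefore show that the estimator chain is consistent under the assumed
hierarchical-Gaussian model, not that real post-stroke data meet those
assumptions.

## Numerical choices

- Trial index coded 1..n_trials (0-based coding changes nothing about
  residuals).
- z-scoring uses the residual sample SD (ddof = 1); the pooled T-score
  mean-50/SD-10 identity is asserted to 1e-6.
- Onset times are snapped to the sampling grid in the simulator so the
  noise-free template reproduces the target exactly.
- Pulse truncation: a drawn pulse whose peak + 3σ overruns the response
  window raises an explicit truncation error rather than silently clipping.
- Physical floors (peak ≥ 5 % of target force, time-to-peak ≥ 20 % of
  target time) guard the Gaussian draws against non-physical tails; at the
  default SDs they are essentially never hit.
- Ties in the trace maximum break to the earliest sample.
- The exact-F null calibration check uses 8,000 Monte-Carlo replicates so
  the binomial standard error (≈ 0.0024) is small against the ±0.01
  calibration band.

## Problem sizes

The shipped analyses and tests use the full study layout (66 + 32
participants × 30 trials, 3,000-sample traces) for single-cohort runs, the
parameter-level fast path (no sampled traces) for 100-replicate
group-separation Monte-Carlo, and 2×2 cells of 12 observations for the
8,000-replicate null-calibration study.

## Known limitations

- The purification regression removes only a *linear* common practice
  trend; participant-specific or nonlinear learning leaks into IIV, as it
  does in the standard ISD methodology.
- IIV estimates from 30 trials carry sampling error with CV ≈
  1/√(2·29) ≈ 13 %; group comparisons inherit it.
- The Welch/pooled gating reproduces common reporting practice but is not a
  claim about any particular published analysis pipeline.
- The sex chi-square on 2×2 counts is sensitive to the continuity
  correction (off by default, flaggable); small-sample exact tests are out
  of scope.
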