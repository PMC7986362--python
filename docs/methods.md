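# Methods

`dialact` re-implements, as a tested pipeline, the accelerometer analysis used
to characterise physical activity and functional behaviours in a haemodialysis
cohort: wrist-worn triaxial accelerometry processed to calibrated
vector-magnitude epochs, dialysis-aware wear QC and imputation, machine-learned
classification of five functional behaviours with hidden-Markov-model time
smoothing, questionnaire scoring, and the cohort statistics (day-type
contrasts, covariate-adjusted marginal means, correlations, time-of-day
profiles, matched-control comparison). Because the original cohort's raw data
are not deposited, a synthetic cohort generator calibrated to the study's
published tables stands in for the participants; every pipeline stage is
validated against that generator's known truth.

## Preprocessing (raw tier)

Raw traces are timestamped x/y/z samples in gravity units (nominally 100 Hz
from an AX3-class device; the package ingests a plain CSV dialect and is
rate-agnostic — synthetic raw data default to 25 Hz with the device rate kept
as metadata).

- **Stationary detection.** Non-overlapping consecutive windows (default 10 s)
  whose per-axis sample sd is below 13 mg on all three axes. Both defaults
  follow the established large-cohort protocol and are configurable.
- **Autocalibration.** Stationary windows should lie on the 1-g gravity
  sphere. A per-axis offset and gain are fitted by iterated least squares:
  each axis of the current calibrated points is regressed on its projection
  onto the unit sphere, and the updates are composed (maximum 100 iterations,
  convergence at < 0.1 mg change in mean absolute radius error). The fit is
  refused — identity returned, flagged unfitted — with fewer than 50
  stationary windows or without both-sign coverage on every axis, and is
  discarded if it fails to reduce the residual or drives a gain outside
  [0.5, 1.5]. Recovery of injected errors is ~0.1 mg / 0.1% on well-spread
  point sets (tested to 1 mg / 0.5% over 20 seeds).
- **ENMO epochs.** Per sample, vm = max(0, ‖(x, y, z)‖ − 1 g), averaged over
  5-s epochs and expressed in milligravity (mg). Truncation (rather than the
  absolute-value variant) is the default because it is the cited protocol's
  energy-expenditure-validated metric; `truncate=False` exposes the
  alternative. ENMO is rotation-invariant by construction (tested to 1e-9).
  Classification uses 30-s epochs; per-minute values average the epochs within
  the minute.
- **Resampling.** Linear interpolation onto a uniform grid at the declared
  rate; gaps longer than 1 s are left missing rather than interpolated.

## Wear QC and imputation

- **Non-wear** is a contiguous stationary run of at least 60 minutes
  (configurable); shorter still periods (naps, rests) remain wear.
- **Day types.** Calendar days are dialysis or non-dialysis by the
  participant's thrice-weekly treatment weekday pattern; partial first and
  last days (device fitting/return) are excluded from all summaries.
- **Excellent wear** (the inclusion criterion): at least 72 h of worn data
  and at least one worn minute in each of the 24 clock hours. Coverage is
  additionally required separately within dialysis days and within
  non-dialysis days; participants failing it are excluded from cohort
  summaries. Hour coverage is assessed across the record (not per day),
  matching the cited protocol's reading; an empty day-type subset (controls)
  is vacuously covered.
- **Imputation** fills each unworn minute with the mean of worn values at the
  same clock minute on the other days of the same day type (the modal state
  for behaviours), so dialysis-session gaps are never filled with
  non-dialysis activity. Minutes with no same-type donor stay missing and are
  excluded from summaries. Worn minutes are never altered.

## Behaviour classification

Five functional behaviours — walking, light tasks, moderate-intensity
activity, sedentary, sleep — are predicted per 30-s epoch.

- **Features.** At raw tier: ENMO mean/sd, per-axis moments and covariances,
  pitch/roll from the gravity direction, dominant frequency and power share,
  fixed band powers, 1-s autocorrelation. At epoch tier the generator's
  class-conditional Gaussian feature vectors pass through unchanged.
- **Balanced random forest.** Each of 100 trees (unlimited depth, √p feature
  subsampling) is grown on a bootstrap in which every class is down-sampled
  to the rarest class's count, so walking (~1 h/day) is not swamped by
  sedentary time. Out-of-bag votes give an honest confusion matrix.
- **HMM smoothing.** The forest's argmax labels are treated as noisy
  observations of a hidden state sequence. Priors and transitions are
  estimated from the labelled training sequences (bigram counts), the
  emission matrix from the OOB confusion; all with an additive pseudo-count
  α = 1 so every matrix is strictly positive for log-space Viterbi decoding.
  Ties break toward the lowest state index. A mode using forest probability
  vectors as likelihoods is available behind the `predict_proba` surface.
  Smoothing exploits the semi-Markov run-lengths of real behaviour and, on
  noisy sequences, raises epoch accuracy substantially (it never reduces it
  on average; property-tested).
- **Training subset.** Mirroring the study's camera validation, the model is
  trained on 25 participants' labelled epochs (2 days each) and applied to
  the whole cohort. At the default feature separation the OOB accuracy is
  ~0.90 and post-smoothing epoch accuracy ~0.99; widening the class overlap
  (`feature_separation` ≈ 1) reproduces a ~74% regime.

## Questionnaires

KCCQ items (6 physical-limitation, 8 symptom, 3 quality-of-life, 4
social-limitation; ordinal 1–5) are rescaled linearly to 0–100 and averaged
per domain when at least half the items are answered; FSS = mean(physical
limitation, symptom), Clinical Status = mean(FSS, quality of life, social
limitation); missing constituents propagate. The exact item counts per domain
are an instrument-convention assumption (the analysis uses only the domain
and composite scores). EQ-5D-3L validates five 3-level domains and a 1–100
VAS; no tariff valuation is applied.

## Cohort statistics

Per-participant summaries (mean vm in mg; state hours/day) are computed by day
type and overall, where *overall* is the mean over all included days (a
wear-time-weighted reading; not the mean of the two day-type means — both
conventions are computable but never silently mixed). Group tables report
mean and SE = sd/√n. Dialysis vs non-dialysis contrasts use classical paired
t-tests. Adjusted comparisons fit outcome ~ group + age + sex + leg weakness
by least squares and report estimated marginal means at the cohort-average
covariate values, with heterogeneity from the group-term F-test and trend
from an ordinal 0/1/2 coding. Questionnaire associations use Spearman rank
correlation (average ranks, two-sided p). Time-of-day profiles average
participant-level curves per clock bin (default 10 min) with 95% CI =
±1.96 SE across participants. No multiple-testing adjustment is applied by
default, mirroring the original analysis's cautious narrative approach; a
Benjamini–Hochberg option (`fdr=True`) is exposed on the correlation table.
Matched controls are selected greedily without replacement in seed-randomised
case order: exact sex and wear season, nearest age within a ±3-year caliper,
up to five controls per case; cases with no eligible control are reported
unmatched.

## Synthetic cohort generator

The generator defines the study conditions; defaults reproduce the published
cohort: n = 73 (22 female, 43 with self-reported leg weakness), 12 complete
wear days plus a partial fitting day, thrice-weekly ~4-h dialysis sessions in
a morning (07:30–11:30) or afternoon (13:00–17:00) slot, and day-type
behaviour profiles of (walking, light tasks, moderate, sedentary, sleep) =
(0.90, 0.57, 0.45, 13.58, 8.50) h on dialysis days and
(1.08, 0.78, 0.64, 12.90, 8.60) h on non-dialysis days. (The published
non-dialysis row sums to 23.99 h from rounding; sleep carries the 0.01 h so
each profile tiles 24 h exactly.) The 3:7 weekly mix of these profiles
reproduces the published all-participants row.

Key calibration choices:

- **Ages** are drawn so the *realized* truncated distribution has the
  published mean 66.5 and SD 14.0 on [26, 87] (the nominal parameters are
  solved numerically; drawing from N(66.5, 14) directly would understate both
  moments).
- **Age gradient.** The published tertile activity means (19.5 / 14.2 /
  12.8 mg at ≤62 / 62–74 / >74 years) are not collinear in age, so the age
  effect is a step profile over the tertile bins with exactly those
  deviations; a linear `age_activity_slope` mode exists for experiments.
  Within-tertile age trends are not modelled (a stated limitation).
- **Leg weakness** subtracts a 5.2 mg deficit (the published 18.6 − 13.4
  contrast), applied around the exact cohort fraction so the cohort mean is
  preserved; leg weakness is drawn independently of age.
- **Participant effect.** A mean-one lognormal multiplier with sd 4.2 mg at
  the cohort reference level (15.6 mg). Multiplicative noise reproduces the
  published pattern of dispersion scaling with activity level (young-group
  sd ≈ 6.9 vs old-group sd ≈ 3.3) and the cohort SE ≈ 0.7 at n = 73.
- **Day level.** Each day's target mean vm is the participant's day-type
  truth plus N(0, 1 mg) day-to-day noise (the paper gives no within-person
  variance; 1 mg is exposed as `day_vm_sd`). State emission means are
  rescaled per day so the schedule-implied expected daily ENMO equals the
  day's target exactly — a single shared set of state intensities cannot
  satisfy both day-types' published (hours, vm) pairs simultaneously, so
  this per-day intensity normalisation is the consistent construction.
- **Schedules** are semi-Markov: night sleep split across midnight (waking
  ~07:00, or ~04:45 before morning dialysis slots, producing the
  characteristic 4–6 a.m. activity), the dialysis block placed sedentary in
  the assigned slot, and the waking remainder tiled with shuffled
  state bouts (typical bout lengths: walking 6, light 12, moderate 10,
  sedentary 35 min) whose daily totals jitter (mean-one lognormal, 15%)
  around the participant's truth.
- **Signal tiers.** Epoch tier (default): 30-s epochs with truncated-normal
  vm, class-conditional Gaussian features (unit sd, configurable
  separation), true labels, and Poisson non-wear gaps (0.15/day, 60–180 min)
  with a truth mask. Raw tier: a slowly precessing gravity unit vector
  (defeats stationarity tests without affecting the norm) scaled by a radial
  oscillation whose amplitude encodes the state's ENMO mean exactly
  (mean of max(0, A sin) = A/π), plus noise perpendicular to gravity
  (second-order ENMO effect only) and optional offset/gain miscalibration.
  Simulating the full cohort at device rate is deliberately refused
  (`max_raw_span_h`): the raw tier validates preprocessing on spans of
  hours, the epoch tier drives cohort-scale runs.
- **Controls** have no dialysis schedule, conventional sleep, a recorded wear
  season, and scenario activity levels: apparently healthy 28.1 mg (n = 318),
  prior CVD/diabetes 23.4 mg (n = 297), heart failure 22.9 mg (n = 172),
  with 5 mg between-control sd and 7 wear days.
- **Questionnaires.** A shared latent mixes standardized true activity with
  noise at a configurable strength (default 0.8); items discretise item-level
  latents into their ordinal scales, higher activity giving better KCCQ and
  lower EQ-5D disability levels, inducing the rank correlations the analysis
  estimates.

What the generator does *not* emulate: real accelerometer artefacts
(temperature drift, clock drift, spikes), within-tertile age gradients,
age-correlated leg weakness, intradialytic micro-movement, seasonal activity
structure, or realistic feature physics at epoch tier (features are abstract
Gaussians). Passing recovery tests therefore demonstrates that the pipeline
is unbiased under the modelled structure, not that the classifier's accuracy
transfers to real devices.

## Numerical choices and degenerate inputs

Viterbi runs in log space with strictly positive matrices (α-smoothed); ties
break to the lowest state index, and distinct maximum-probability paths can
tie exactly, so the oracle test asserts membership in the exhaustively
enumerated argmax set. Minute-state majority votes break ties toward the
earlier epoch. Calibration on degenerate geometry (few windows, one
orientation, non-reducing fit) returns an unfitted identity rather than
failing. Paired t-tests with zero-variance nonzero-mean differences report
the machine floor with a `degenerate` flag. Empty groups are omitted from
tables with single-member groups reporting a missing SE.

## Problem sizes

Default end-to-end runs use the full study conditions: 73 participants × 12
complete days of 30-s epochs (≈2.6 M epochs), a 25-participant × 2-day
labelled training subset, and a 318-control pool at 7 days. A full cohort
recovery run completes in ~1.5 minutes on one CPU; the test suite adds one
such run for the acceptance checks.

## Known limitations

Epoch-tier features are statistically, not physically, generated, so absolute
classifier accuracy on synthetic data is a function of the configured
separation. Daylight-saving transitions are not modelled (all timestamps are
naive local clock time); behaviour on DST days is undefined and flagged as an
open issue rather than guessed. EQ-5D tariffs, ECG waveform analysis and
camera image handling are out of scope by design.
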