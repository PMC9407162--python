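# Methods

This note documents the models and procedures implemented in `mssense`,
their assumptions, the tunable parameters with defaults, and the design
choices made where the design was genuinely open.

## Study design assumed by the pipeline

A cohort of participants is observed over a study window split by a single
calendar boundary into a *pre* period and a *stay-at-home* period (defaults:
2019-11-16 to 2020-05-15 with the boundary at 2020-03-23, giving 128 and 53
days; all intervals are half-open `[start, end)`). Six sensor streams are
collected per participant — calls and screen as timestamped events; location
at 1 fix / 10 min; heart rate, sleep status and steps at 1 sample / min.
Four patient-reported instruments are administered on fixed cadences (PHQ-9
every 14 days; MSRS-R, MFIS-5 and PSQI every 28 days). Timestamps are naive
local time; no daylight-saving modeling.

## Synthetic cohort generator

Each virtual participant carries baseline behavioral parameters (home/work
coordinates, bed time ~N(23:00, 45 min), sleep duration ~N(465, 40 min),
resting heart rate ~N(65, 5 bpm), daily step budget ~N(8000, 2000),
call rate ~LogN(log 6, 0.4) per day, screen episodes ~N(40, 10) per day,
propensity to leave home ~N(1.0, 0.8) on the logit scale) and a latent
severity per outcome from a one-factor model (loadings 0.7 / 0.6 / 0.7 /
0.5 for depression / burden / fatigue / sleep quality), so the four
outcomes are positively inter-correlated as real patient-reported outcomes
are. Binary ground-truth labels threshold the severities at the configured
prevalence (default 0.5 each).

Behavior is simulated bottom-up per minute or per 10-minute slot: a main
sleep episode per night with restless/awake interruptions and rare
`unknown` statuses; steps as a two-state (active/sedentary) minute process
calibrated to the day's budget, with occasional 30-minute workouts; heart
rate as resting rate + activity coupling + daytime elevation + N(0,3),
clamped to [30, 220] bpm; location as a home/work/errand schedule with 9 m
GPS noise; calls and screen-unlock episodes as daily Poisson processes with
daytime-weighted timing.

The stay-at-home mandate shifts *everyone* (leave-home logit −1.5, step
budget ×0.85, +5 screen episodes/day). Outcome-linked effects additionally
shift the stay-period parameters of positive-label participants, expressed
in units of the between-participant SD of each parameter. Defaults (the
"strong planted signal" condition):

| outcome    | shifted parameters (SD units) |
|------------|-------------------------------|
| depression | call rate +1.5, resting HR −1.5, leave-home −1.5 |
| msrsr      | step budget −1.5, leave-home −1.0, restlessness +1.0 |
| mfis5      | step budget −1.0, sleep duration +1.5, screen rate −1.0 |
| psqi       | restlessness +1.5, bed time +1.0, screen rate +1.0 |

Shifts act only on records dated on/after the boundary; each sensor draws
from its own spawned generator and fixed-count draws precede
parameter-dependent ones, so pre-period records are bit-identical whether
or not shifts are configured (this is asserted by a test). Questionnaire
totals track latent severity at 3 points per SD around each instrument's
dichotomization threshold with ±1-point label margin and N(0, 1.5)
administration noise, so period-averaged scores reproduce the generative
labels ≳ 90% of the time. Missingness: per-sensor whole-day dropout
(default 3%), within-day 1–4 h gaps on 5% of days for sampled streams, and
a configurable fraction of participants (default 6/56) whose pre-period
data are removed to exercise the eligibility rule.

What the generator does **not** emulate: GPS noise ellipses and drift,
phone-vs-wearable clock skew, vendor export quirks, seasonal and weekday
behavioral drift unrelated to the mandate, informative (outcome-dependent)
missingness. Passing tests therefore demonstrate correctness of the
pipeline's mechanics and its statistical discipline, not field performance
on real cohorts.

## Coverage and missing data

A sampled sensor-day is valid when ≥ 50% of its expected samples are
present (1440/day for heart and steps, 144 for location, 360 for sleep —
sleep is only recorded during episodes, so its expectation is a minimal
main-sleep length). Event-stream days (calls, screen) are valid when any
screen event exists that day, a phone-alive proxy. A participant is
eligible when some sensor has ≥ 7 valid days in *each* period; a sensor's
features are usable for a participant when that sensor has ≥ 7 valid days
in both periods, and are otherwise missing (imputed fold-aware during
modeling, with training-fold medians). All thresholds are configurable
(`CoverageThresholds`).

## Features

Daily features are computed inside each time-of-day epoch (night 00–06,
morning 06–12, afternoon 12–18, evening 18–24, half-open) on valid days
only; the day-of-week set of a temporal slice restricts which daily rows
enter the period average. Per-sensor catalogs (the column ordering
authority) are in `features.FEATURE_CATALOG`: calls (6), screen (4),
location (8), steps (4), sleep (7), heart (6) — 35 features × 15 slices per
participant across six per-sensor matrices. Event features attribute calls
to their start time and screen episodes (unlock → next lock/off) to the
unlock time. Counts and totals are 0 on phone-alive days without events;
means and maxima stay missing.

Location: variance is computed on raw degrees (log of lat+lon variance),
travel distance by haversine over consecutive fixes, radius of gyration on
a centroid-centered equirectangular projection. Places are single-linkage
clusters (fixes linked within 30 m; components with ≥ 3 fixes), computed
per slice-day for `n_places`/entropy and once per participant (with a 6 m
grid snap for speed) for global place identities; *home* is the global
place holding the most night-epoch fixes. `regularity_24h` is the mean
Pearson correlation between consecutive days' hourly dominant-place-id
vectors, restricted to the epoch's hour bins; days observing fewer than
half the epoch's bins are excluded, calendar-adjacent pairs only, and a
pair of constant identical vectors counts as r = 1 (a constant routine is
perfectly regular) while constant different vectors count 0. Activity
thresholds: active ≥ 60 steps/min, sedentary < 10 steps/min with bouts
≥ 30 min; heart-rate exercise zone boundary 0.5 × (220 − age) with a
configurable age (default 40). Sleep minutes belong to the calendar day
they occur in (episodes split at midnight); onset/offset are the first/last
asleep minute of the day-slice.

Behavior change is stay-average minus pre-average, exactly, per slice and
feature; missing when either side is missing.

## Outcomes

Administration totals are item sums (PSQI at the 7-component level; the
19-item scoring algorithm is out of scope). Stay-period administrations
(boundary date inclusive) are averaged and dichotomized at 5 / 6.4 / 8 / 9
(inclusive). Outcome inter-correlations are Pearson r with two-sided
p-values over participants with all four averages.

## Nested stability selection

Randomized-L1 logistic regression: in each of 100 resamples, draw a
stratified 75% row subsample, scale each feature's penalty by an
independent draw from {α, 1} with weakness α = 0.5 (implemented by column
scaling, which is equivalent and leaves the sparsity pattern meaningful),
fit an L1-penalized logistic regression at base strength C = 1, and mark
non-zero coefficients; a feature is selected when marked in ≥ π = 0.4 of
resamples (ties inclusive). The nested variant runs this per temporal-slice
group and then once more on the concatenated survivors.

The resample fits are solved by a batched proximal-gradient (FISTA)
L1-logistic solver written for this package (exact zeros via
soft-thresholding, unpenalized intercept, step from the per-resample
spectral norm, ≤ 300 iterations to 1e-6); all resamples solve in one
vectorized pass. `StabilityConfig(solver="liblinear")` routes every
resample through scikit-learn instead; a test asserts the two routes'
selection frequencies agree.

Operating point: π = 0.4 with C = 1 is deliberately permissive. The nested
second stage receives many highly correlated slice copies of the same
behavioral signal, and L1 splits selection support across copies, so a
classic strict threshold (0.6–0.9) returns empty sets for genuinely
informative sensors. The permissive point keeps nested recall while false
selections remain controlled *in the presence of signal* (competition for
the L1 budget): on the planted benchmark (10 informative of 200, 1.5 SD
class shift, n=100) recall ≈ 0.98 with ≈ 1 false selection. On pure noise
the same point selects freely — null protection comes from the
cross-validated evaluation, not from the selector, and the zero-effect
cohort check verifies it.

## Models, stacking, ablation

Candidates per sensor: L2 logistic regression with C ∈ {0.01, 0.1, 1, 10},
and gradient boosting with {50, 100} trees × depth {2, 3} at learning rate
0.1 (tree counts evaluated from one staged fit per depth). Within each
training fold the winning configuration is chosen by F1 on an inner
stratified 75/25 split; the winner is refit on the full training fold for
test predictions, and an inner leave-5-participants-out pass (leave-one-out
when the training fold is very small) produces the *training-side*
detection probabilities for stacking. Empty selections degrade to a
constant model emitting the training prevalence.

The late-fusion ensemble is AdaBoost over gradient-boosting base learners
(30 trees, depth 3, learning rate 0.3 — a strong base, so boosting usually
terminates after one stage on n ≈ 50 training rows). `n_estimators` is
tuned over {5, 10, 20, 30, 50} by staged evaluation on an inner stratified
split, skipped when boosting terminated at one stage (all grid values then
coincide). The ablation trains one ensemble per sensor combination (57 for
six sensors, enumerated by size then lexicographically) under the shared
fold plan; the best combination maximizes pooled F1, ties broken by
accuracy, then fewer sensors, then enumeration order. Decision threshold
0.5 throughout.

Fold discipline: selection, imputation statistics, hyperparameter choice
and stacking inputs are computed from training-fold rows only; the harness
records the participant sets used at each step and a test audits their
disjointness from the test block.

## Cross-validation and metrics

Outer validation is leave-5-participants-out with test blocks stratified by
outcome label (`StratifiedKFold` with ⌈n/5⌉ shuffled splits): with
prevalence near 0.5, unstratified blocks make the pooled majority baseline
anticorrelate with the held-out block composition (observed ≈ 0.41 at 0.5
prevalence), which misrepresents the baseline; stratification restores
baseline ≈ majority-class share at every prevalence. Metrics (accuracy,
precision, recall, F1 for the positive class; 0 when a denominator is 0)
are pooled over folds into one confusion matrix — pooled metrics are stable
for 5-participant blocks. The baseline predicts each fold's
training-majority class (ties → positive). Improvement is
(accuracy − baseline) / baseline × 100.

Interpreting the best-of-57 report: it is a maximum over correlated models,
so on null data its accuracy sits ~1.5–2 pooled-CV standard errors above
its expectation (≈ +0.10 at n ≈ 55) without any leakage; null checks
therefore average over the four outcomes.

## Mediation

OLS with intercepts: M1 ~ X, M2 ~ X, Y ~ X + M1 + M2, Y ~ X; indirect
effects are coefficient products, and c = c′ + a₁b₁ + a₂b₂ holds exactly
for the point estimates on any sample. Confidence intervals are
bias-corrected (not accelerated) percentile bootstrap with case resampling,
default 5000 replicates at 95%: z₀ = Φ⁻¹(fraction of bootstrap estimates
below the point estimate), limits at the bootstrap quantiles
Φ(2z₀ ± z_{α/2}). The acceleration term is omitted for simplicity; at the
n used here its effect on coverage is within the Monte-Carlo noise of the
coverage test. Bootstrap regressions are solved batched (normal equations
over a resample axis, in chunks of 512). Collinear mediators and
zero-variance inputs raise errors; n ≥ 10 is required.

## Problem sizes

End-to-end checks run on 60-participant cohorts over a 6-week pre / 4-week
stay window — large enough that every sensor has well-estimated period
averages (≥ 28 daily values per slice average) while a full four-outcome
run with the 57-combination ablation completes in minutes on one core.
The acceptance script uses the default study calendar (128 + 53 days) at
the default cohort size of 56. Selection benchmarks use n = 100 with 200
features; mediation consistency uses n = 5000 and coverage n = 200 with
500-replicate bootstraps over 200 simulations.

## Known limitations

- The feature catalog is a fixed, literature-conventional set; real
  deployments often add conversation/audio and app-usage features.
- The PSQI is handled at the component level; item-level scoring rules are
  not implemented.
- Pure-noise false-selection control is deliberately traded for nested
  recall (see the selection operating point above).
- The mediation model takes no covariates and assumes linear, homoscedastic
  relations among period-averaged scores.
- Synthetic-data realism limits are listed in the generator section; none
  of the reported synthetic performance numbers transfer to real cohorts.
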