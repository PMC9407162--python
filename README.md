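# mssense

Passive-sensing behavior-change analysis for predicting patient-reported
outcomes in people with multiple sclerosis (MS).

During a disruptive event such as a stay-at-home mandate, behavior measured
passively by smartphones (calls, screen use, location) and fitness trackers
(heart rate, sleep, steps) changes — and *how much it changes* carries
signal about a person's mental and neurological health. `mssense`
implements, as a tested and reusable pipeline, an analysis that:

1. extracts daily behavioral features from six raw sensor streams inside 15
   **temporal slices** (five time-of-day epochs × three day-of-week sets);
2. forms **behavior-change features**: the stay-at-home-period daily average
   minus the pre-period daily average of each feature,
   Δf = f̄<sub>stay</sub> − f̄<sub>pre</sub>;
3. scores and dichotomizes four patient-reported outcomes — depression
   (PHQ-9 ≥ 5), global MS symptom burden (MSRS-R ≥ 6.4), fatigue
   (MFIS-5 ≥ 8) and sleep quality (PSQI ≥ 9), each averaged over the
   stay-at-home period;
4. selects features per sensor by **nested randomized-L1 logistic
   regression** (stability selection within each temporal slice, then again
   on the concatenated survivors), strictly inside each training fold;
5. trains one model per sensor (logistic regression vs gradient boosting),
   stacks the six positive-class detection probabilities into an AdaBoost
   ensemble with gradient-boosting base learners, and runs a **57-combination
   sensor ablation** (all subsets of size ≥ 2 of six sensors) under
   leave-5-participants-out cross-validation with a majority-classifier
   baseline;
6. quantifies, by **parallel two-mediator mediation** with bias-corrected
   bootstrap confidence intervals, how much of the association between
   symptom burden (X) and depression (Y) flows through fatigue (M1) and
   sleep quality (M2): indirect effects a₁b₁ and a₂b₂ with
   c = c′ + a₁b₁ + a₂b₂.

Because the cohort data such an analysis is built on are private, the
package ships a first-class **synthetic cohort generator** that simulates
raw streams at the real sampling rates (location 1/10 min; heart, sleep,
steps 1/min; calls and screen as events), questionnaire administrations at
the real cadences, realistic missingness, and outcome-linked behavior
shifts injected at the generative-parameter level. Every downstream stage
is testable end to end without any data download.

Intended users: researchers in digital phenotyping / mobile-sensing health
analytics who want a reference implementation of slice-based behavior-change
prediction, and methodologists who need a controllable synthetic benchmark.

## Worked example

Simulate a 60-participant cohort with strong planted behavior shifts
(the generator defaults) over a 6-week pre-period and 4-week stay-at-home
period, and run the full pipeline:

```python
import datetime
from mssense import CohortConfig, PipelineConfig, run_pipeline

cohort = CohortConfig(
    n_participants=60, seed=7,
    study_start=datetime.date(2020, 1, 6),
    period_boundary=datetime.date(2020, 2, 17),
    study_end=datetime.date(2020, 3, 16),
)
result = run_pipeline(PipelineConfig(cohort=cohort, seed=11))
for outcome, res in result.results.items():
    print(outcome, "baseline", round(res.baseline["accuracy"], 3),
          "best", res.best["sensors"],
          "acc", round(res.best["accuracy"], 3),
          "f1", round(res.best["f1"], 3),
          "improv", round(res.best["improvement_pct"], 1))
```

Output (about 10 minutes on one core):

```
depression baseline 0.574 best heart+location+sleep acc 0.981 f1 0.978 improv 71.0
msrsr baseline 0.537 best heart+sleep+steps acc 0.889 f1 0.893 improv 65.5
mfis5 baseline 0.593 best heart+location+sleep acc 0.889 f1 0.864 improv 50.0
psqi baseline 0.519 best screen+sleep acc 0.926 f1 0.92 improv 78.6
```

Reading: for each outcome, `baseline` is the pooled accuracy of a majority
classifier refit per fold, `best` names the sensor combination whose
stacked ensemble had the highest cross-validated F1, `acc`/`f1` are its
pooled leave-5-participants-out performance, and `improv` is the relative
accuracy improvement over baseline in percent. With strong planted shifts
the pipeline recovers the labels far above baseline; with
`CohortConfig(effect_size={})` (a null cohort) best-model accuracy stays
within noise of the baseline.

A CLI mirrors the library: `mssense simulate --out DIR`,
`mssense run --simulate cfg.yaml --seed 11 --out DIR`, and
`mssense mediate --data DIR --boundary 2020-03-23`.

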