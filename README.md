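# symburden

Estimating daily symptom burden during outpatient chemotherapy from
passively sensed mobile-phone and wearable data.

Cancer patients on chemotherapy experience strongly fluctuating physical
and psychological symptoms, and asking them to rate 12 symptoms twice a
day does not scale to months of treatment. This package implements the
full analysis pipeline for the alternative: infer each day's symptom
burden from what the phone and a wrist-worn tracker already record —
movement, location, screen and app use, communication, steps and sleep.
It is written for researchers in digital phenotyping / mHealth
biostatistics who want every stage of that pipeline testable offline.

The pipeline:

1. **Ingestion** (`symburden.ingest`) — documented CSV dialects for raw
   accelerometer, GPS, activity-recognition, screen, app, battery and
   hashed call/SMS streams plus Fitbit-style daily, minute and sleep
   records; validation with malformed-row accounting; slicing into
   midnight-to-midnight patient-days with interval events split at
   midnight.
2. **Features** (`symburden.features`) — a closed registry of 50
   day-level features: accelerometer magnitude statistics, activity
   counts, DBSCAN location clusters with dwell time, location entropy
   −Σ pᵢ ln pᵢ and radius of gyration √(Σ pᵢ d(cᵢ, c̄)²), sedentary and
   active step bouts, sleep summaries, screen/app/charge durations and
   communication counts — with explicit missingness throughout.
3. **Labels** (`symburden.labels`) — daily burden = Σ over 12 symptoms of
   the day's mean 0–10 severity (range 0–120); per-patient mean-centering;
   classes low/normal/high as the residual is <0, =0, >0 (an epsilon band
   is available).
4. **Screening and selection** (`symburden.correlations`,
   `symburden.selection`) — pairwise-complete Pearson r of each feature
   against burden; correlation-based feature subset selection (CFS) with
   merit k·r̄_cf/√(k+k(k−1)·r̄_ff) and best-first search.
5. **Classification** (`symburden.classify`) — a rotation forest
   (block-diagonal PCA rotations over random feature subsets, 100-tree
   random-forest base learners, majority vote) with class-balancing
   resampling, evaluated as a population model (stratified 10-fold CV)
   and as individual models (leave-one-day-out per patient), in both a
   leakage-free order and the conventional resample-before-folding order.
6. **Synthetic cohort** (`symburden.synthetic`) — since no raw patient
   data of this kind is deposited, a generator emulates the study design:
   a latent AR(1) daily burden per patient drives both the symptom
   ratings and, through a tunable `coupling`, the behavioral streams
   (fewer, weaker steps in more fragmented bouts; less and less variable
   phone acceleration; longer screen interaction in fewer sessions; more
   sleep with more awakenings). `coupling = 0` is an exact null.

`docs/methods.md` describes the model, parameters and limitations;
`analysis/01…08` are the numbered study drivers; `symburden.experiments`
holds the reusable experiment code they share with the tests.

## Worked example

```sh
python analysis/01_simulate_cohorts.py   # raw streams -> scratch/cohorts/
python analysis/03_build_labels.py
python analysis/06_population_model.py
```

prints, for the strong-coupling cohort (10 patients × 30 days, seed 3):

```
300 labeled patient-days, 10 patients
burden score: mean 15.9, range 2.0-41.5
class counts: {-1: 155, 1: 145}

replication_all               91.0%
replication_selected          90.0%
leakage_free_all              77.3%
leakage_free_selected         82.0%
null_control                  50.5% (majority 52.2%)
```

Read: the burden composite sits at the intended level (mean ~16/120).
Under the conventional order of operations (class-balancing resample of
the whole dataset before cross-validation, "replication") the population
model classifies 91.0% of days as low vs high burden, and 90.0% with only
the CFS-selected feature subset — within one point. With resampling and
selection kept strictly inside training folds the honest estimate is
77.3% (82.0% selected); the gap is the leakage of the conventional
procedure, reported rather than hidden. On an uncoupled control cohort
accuracy stays at the majority-rate chance level. For reference, an
oracle reading the true latent state achieves ~89% — close to the
replication-mode figure.

`analysis/04_correlation_screen.py` shows the designed directions at the
day level (number of sedentary bouts r = .90, accelerometer SD −.86,
steps −.81, interaction duration +.84, minutes asleep +.95, …), and
`analysis/07_individual_models.py` fits per-patient leave-one-day-out
models (mean 86.0% across patients on the same cohort).

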