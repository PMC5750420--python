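# Methods

## Problem and data model

Patients undergoing outpatient chemotherapy experience strongly fluctuating
physical and psychological symptoms. The package estimates each day's
*symptom burden* — the sum over 12 symptoms (pain, fatigue, feeling
disconnected, trouble concentrating, sadness, anxiety, anhedonia,
irritability, shortness of breath, numbness, nausea, poor appetite) of the
day's mean 0–10 severity rating — from passively sensed phone and wearable
data, so that severe or worsening days can be flagged without asking the
patient anything.

The unit of analysis is the **patient-day**: all events of one patient in
one midnight-to-midnight window of local time. The window is half-open,
`[00:00, 24:00)`; an event stamped exactly at midnight opens the new day.
On daylight-saving transition days the window is 23 or 25 h and all
rate-type features divide by the actual monitored minutes rather than 1440.
Interval events (screen-interaction sessions, app foreground sessions,
battery charges) are reconstructed from their point events on the full
stream first and then split at midnight, so each side of the boundary is
credited with exactly its share; the split conserves total duration.

Timestamps are stored as UTC instants plus a patient timezone and converted
only for windowing. Session logs truncate in practice, so an unpaired
session start is closed at the earliest of its own end event, the next
session start (for app sessions: of *any* app, since only one app is
foreground at a time), or the end of its day — the error is bounded by one
day.

## Day-level features

One `FeatureVector` per patient-day carries every feature in a closed
registry (50 features over 8 sources). A feature is *missing* (NaN) iff its
source stream is absent for that patient, its inputs are insufficient, or
its denominator is zero; it is never silently zero-filled. With the stream
present but empty, counts are genuine zeros.

* **Phone accelerometer** — min, max, mean, median and SD of the per-sample
  Euclidean magnitude (m/s²). SD uses the sample (n−1) convention and is
  missing below two samples. The statistics are invariant to sample order
  and, in expectation, to emission rate.
* **Activity recognition** — number of distinct activity labels observed,
  modal activity, number of label changes between consecutive events.
  "Number of activities" counts *distinct labels* (the raw event count is a
  cadence artifact); the raw-count reading remains computable from the
  stream. Modal ties break lexicographically, deterministically.
* **Location** — GPS fixes are density-clustered per day with DBSCAN over
  great-circle distance (haversine, R = 6 371 000 m), eps = 100 m,
  min_samples = 5. Dwell credited to a fix is the gap to the next fix
  capped at 30 min, because fused location providers emit sparsely while
  stationary and uncapped gaps overweight the last fix of a stay. Per-day
  clusters merge across days into *global locations* (nearest existing
  global centroid within the eps radius, dwell-weighted running mean;
  otherwise a new global). Features: number of day clusters, time at the
  patient's overall most-visited global location that day (a per-day-top
  variant is available), location entropy −Σ pᵢ ln pᵢ over the day's dwell
  fractions (natural log, fixed so tests are exact), radius of gyration
  √(Σ pᵢ d(cᵢ, c̄)²) with the dwell-weighted centroid c̄, and the summed
  great-circle distance between consecutive fixes.
* **Wearable activity** — daily totals passed through (steps, distance,
  floors, lightly/fairly/very active minutes) plus minute-level structure:
  maximum steps per minute, and sedentary/active *bouts* — maximal runs of
  minutes with zero / at least one step. Coverage gaps terminate bouts.
  Per kind: count and min/max/mean length; for active bouts also max and
  mean steps per bout. Bout lengths partition the covered minutes and the
  kinds alternate.
* **Sleep** — minutes asleep, minutes awake, number of awakenings, minutes
  in bed, attributed to the day the episode ends (the morning). A record
  claiming more sleep+wake than time in bed (beyond 1 min) is kept with an
  integrity warning.
* **Phone usage** — total screen-interaction time (unlock → lock/off),
  unlocks per monitored minute, total app foreground time, app launches per
  minute, unique apps, changes between distinct consecutive foreground
  apps, charging duration.
* **Communication** — counts and durations of incoming/outgoing calls,
  missed calls, incoming/outgoing SMS, unique hashed correspondents, and
  the modal correspondent hash (ties: lexicographically smallest).

Two features are categorical (modal activity, modal correspondent). In the
numeric matrix they are integer-encoded (fixed vocabulary index; stable
CRC bucket for hashes); they are excluded from Pearson screening.

## Labels

Daily burden = Σ over the 12 symptoms of the mean severity across that
day's (up to two) prompts, range 0–120. Per patient, the series is centered
on the patient's own mean; a day is classed −1 / 0 / +1 as the residual
falls below, inside, or above a band of half-width `epsilon` around zero.
`epsilon = 0` is the default (the literal sign rule); with real-valued
scores the 0 class then occurs only on exact ties, so a positive band is
exposed for a non-degenerate 3-class problem. Classes are invariant to
adding a constant to a patient's whole series. Patients with one labeled
day cannot be centered and are excluded with a warning, and only days with
both sensor and symptom data enter the labeled dataset.

## Correlation screen

Each numeric feature is correlated with the continuous burden score over
pairwise-complete days (N legitimately varies per feature with sensor
availability). Two-sided p-values use t = r√((n−2)/(1−r²)) on n−2 df. No
multiple-testing correction by default (the screen is descriptive;
Benjamini–Hochberg is available behind a flag). Repeated days within a
patient violate independence, so the p-values are naive — this replicates
the conventional analysis and is a known limitation.

## Feature selection (CFS)

Merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff) with mean absolute feature–class
and feature–feature correlations; undefined correlations count 0.
Feature–class correlation treats the class {−1,0,1} as numeric (ordered,
equally spaced severity levels); a symmetrical-uncertainty mode (3-bin
equal-frequency discretization) is available as the information-theoretic
alternative. Search is best-first forward selection from the empty set,
expanding the open subset of highest merit by one feature, stopping after
5 consecutive non-improving expansions; ties break lexicographically, so
the search is deterministic. Best-first is heuristic: on random ≤12-feature
instances it attains the exhaustive-search merit in ≥95% of cases (checked
by test).

## Classifier

A rotation forest with random-forest base learners. Per ensemble member the
features are randomly partitioned into disjoint subsets of 3; per subset,
a bootstrap subsample of a random non-empty class subset (75% of rows,
with replacement) yields a covariance matrix whose full eigenbasis forms
that block of a block-diagonal orthonormal rotation — all components are
retained, a pure rotation with no truncation (an eigendecomposition of the
PSD covariance always yields a complete orthonormal basis even when the
subsample is rank-deficient). The base learner is a 100-tree random forest
trained on the rotated data; defaults are 10 members, subset size 3,
unlimited depth. Prediction is majority vote across members; ties resolve
by greatest mean vote share, then the lower class. Missing values are
imputed with per-feature medians fitted on the training data only (an
all-missing feature imputes 0). Every fit and evaluation is a pure
function of (inputs, seed).

Class imbalance is handled by resampling with replacement to near-uniform
class counts (per-class counts within 1 of ⌊n/3⌋, remainder seats to the
largest classes); requesting an absent class is an error so a caller can
drop to 2-class mode explicitly.

### Evaluation schemes

* **Population model** — stratified k-fold CV (k = 10) pooled over all
  patients' days. Folds are built by per-class round-robin dealing; k is
  lowered only when even the largest class cannot fill k folds, and a
  class rarer than the fold count simply appears in that many folds
  (lowering k to a near-empty class's size would destroy CV for everyone).
* **Individual models** — leave-one-day-out CV per patient (≥5 labeled
  days and ≥2 classes required). When removing the held-out day leaves a
  single-class training set, the fold predicts the training majority.
* **Ablation** — the population model re-run per device/category feature
  group (fitbit, phone, movement, activity, location, phone usage,
  communication), each with all group features and with CFS selection.

Two orders of operations are first-class. In **leakage-free** mode
(default) resampling, selection and imputation are fitted inside training
folds only. In **replication** mode resampling (and selection) are applied
to the full dataset *before* folding — the order small mHealth studies
conventionally describe. Resampling with replacement before folding places
copies of the same day on both sides of a split and inflates accuracy;
both modes are reported so the difference is measurable rather than
hidden. On the strong-coupling cohort the replication-mode estimate
(~90%) closely matches the oracle that reads the true latent state
(~89%), while the leakage-free estimate is lower (~77–82%).

## Synthetic cohort

No raw data from studies of this kind is publicly deposited, so the
generator emulates the study design: configurable cohort size (default
10 patients × 21–30 days, ~2 chemo cycles), twice-daily 12-symptom ratings
with a skip probability per prompt (prompt compliance is a free parameter,
not an estimate), and per-patient stream dropout
(`missing_stream_prob`, default 0.1) so sensor availability varies across
patients as it does in the field.

A latent daily burden drives everything: patient mean ~ Normal(16, 4)
(clipped; the composite's empirical level is ~16/120) plus a stationary
AR(1) deviation (φ = 0.6, sd 8). Between-patient mean differences are
present but must be irrelevant — the labels center per patient. Ratings
are the latent burden split over the 12 symptoms by a fixed weight
profile, plus Normal noise (sd 1), rounded and clipped to 0–10.

The `coupling` parameter scales how behavior responds to the standardized
latent burden, with the directions reported for chemotherapy and
depression symptom studies: on high-burden days, fewer and less intense
steps in more fragmented activity (more sedentary bouts, lower max
steps/min), smaller and less variable phone acceleration, fewer but much
longer screen sessions (interaction duration up, unlocks and app launches
per minute down), fewer fairly/very-active minutes, longer sleep with more
awakenings, a larger at-home dwell fraction, and fewer missed calls.
`coupling = 0` severs every link, giving an exact null. Presets: null
(0), low (0.7), strong (2.0 with behavior noise ×0.4 and patient-mean sd
3, calibrated so every designed day-level |r| ≥ 0.4). GPS clusters are
planted per patient (home/clinic/other, Gaussian jitter σ ≈ 30 m) so
DBSCAN recovery is unambiguous; correspondents come from a 10-hash pool
per patient.

What the generator does **not** emulate: realistic human mobility beyond
a few planted places, app taxonomies, heart rate or calories (excluded
from the analysis scope), weekly/treatment-cycle periodicity, and
behavior-to-behavior dependence beyond the shared latent state. Passing
tests therefore show the pipeline recovers a planted monotone
symptom→behavior coupling at realistic noise levels — not that real
chemotherapy data carries this much signal.

Determinism: one `SeedSequence` per cohort, spawned per patient; the same
config and seed reproduce byte-identical stream files (timestamps at
millisecond resolution, canonical float formatting).

## Problem sizes and numerical choices

Experiment drivers use the design size of 10 patients × 30 days
(~300 labeled days, matching the scale of a ~14-patient/295-day field
study) and emit the accelerometer at 1/60 Hz — magnitude statistics are
rate-invariant in expectation, and the `CohortConfig` default remains
1 Hz. Simulation sweeps (null control, coupling curve, per-patient
models) use a reduced ensemble (3 members × 30 trees); single headline
evaluations use the full default (10 × 100). Tolerances: real-valued
feature oracles agree to 1e−9; residual means vanish to 1e−9; merit ties
use a 1e−12 improvement threshold. Degenerate inputs (empty streams,
single samples, single-class patients, all-zero correlations) each have a
defined behavior — missing values, exclusion with a warning, or a named
error — listed in the module docstrings.

## Known limitations

* The replication evaluation mode is intentionally leaky; its numbers
  characterize the conventional procedure, not generalization.
* P-values in the correlation screen ignore within-patient clustering.
* With `epsilon = 0` the "normal" class is nearly empty, so the 3-class
  problem is effectively 2-class on continuous scores.
* Global-location matching is greedy and order-dependent across days;
  with well-separated planted clusters this is immaterial, but real
  adjacent venues within 100 m can merge.
* The generator's missingness is independent per patient-stream; real
  dropout is correlated (device abandonment, sync failures).
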