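"""Individual models: leave-one-day-out cross-validation per patient.

Each patient gets their own rotation forest, evaluated by holding out
one day at a time, with and without per-fold CFS selection. Writes the
per-patient table (days, accuracy, accuracy with selected features,
selected feature names) to ``results/individual_models.csv``.
"""

from _common import EVAL_SEED, RESULTS, ensure_dirs, strong_cohort
from symburden.experiments import individual_models_experiment, light_config
from symburden.pipeline import cohort_dataset
from symburden.reporting import render_table_individual

ensure_dirs()
ds, _, _ = cohort_dataset(strong_cohort())
reports = individual_models_experiment(ds, light_config(), seed=EVAL_SEED)
table = render_table_individual(reports)
table.to_csv(RESULTS / "individual_models.csv", index=False)

print(table.drop(columns=["selected_features"]).to_string(index=False))
avg = table.iloc[-1]
print(f"mean accuracy {avg['accuracy_pct']}% -> "
      f"{avg['accuracy_selected_pct']}% with selected features")
print(f"wrote {RESULTS / 'individual_models.csv'}")
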