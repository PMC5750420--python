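"""Device/category ablation: which sensors carry the signal?

Re-evaluates the population model restricted to each device (Fitbit vs
phone) and phone feature category (movement, activity, location, phone
usage, communication), with all group features and with CFS selection.
Writes ``results/ablation.csv``.
"""

from _common import EVAL_SEED, RESULTS, ensure_dirs, strong_cohort
from symburden.classify import ablation_by_source
from symburden.experiments import light_config
from symburden.pipeline import cohort_dataset
from symburden.reporting import render_table_ablation

ensure_dirs()
ds, _, _ = cohort_dataset(strong_cohort())
reports = ablation_by_source(ds, config=light_config(), seed=EVAL_SEED)
table = render_table_ablation(reports)
table.to_csv(RESULTS / "ablation.csv", index=False)

print(table.to_string(index=False))
print(f"wrote {RESULTS / 'ablation.csv'}")
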