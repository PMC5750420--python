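"""Build the daily symptom-burden composite and 3-class labels.

Sums the 12 per-symptom daily means into a 0-120 burden score, centers
each patient on their own mean and classifies days as low (-1), normal
(0) or high (+1) burden. Writes ``results/labels.csv``.
"""

from _common import RESULTS, ensure_dirs, strong_cohort
from symburden.labels import build_labels
from symburden.pipeline import write_labels_csv

ensure_dirs()
cohort = strong_cohort()
labels = build_labels(cohort.symptoms, tz=cohort.config.timezone)
write_labels_csv(labels, RESULTS / "labels.csv")

print(f"{len(labels)} labeled patient-days, "
      f"{labels['patient_id'].nunique()} patients")
print("burden score: mean %.1f, range %.1f-%.1f" % (
    labels["burden_score"].mean(), labels["burden_score"].min(),
    labels["burden_score"].max()))
print("class counts:", labels["klass"].value_counts().sort_index().to_dict())
print(f"wrote {RESULTS / 'labels.csv'}")
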