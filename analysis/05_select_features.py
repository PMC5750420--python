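"""Correlation-based feature subset selection on the full dataset.

Best-first CFS search: the selected subset is strongly related to the
burden class but internally non-redundant. Writes
``results/selected_features.json`` (ordered names + merit + mode).
"""

import json

from _common import RESULTS, ensure_dirs, strong_cohort
from symburden.pipeline import cohort_dataset
from symburden.selection import cfs_search

ensure_dirs()
ds, _, _ = cohort_dataset(strong_cohort())
res = cfs_search(ds)
payload = {"selected_features": res.selected_features,
           "merit": round(res.merit, 6), "mode": res.mode,
           "n_subsets_evaluated": len(res.trace)}
(RESULTS / "selected_features.json").write_text(
    json.dumps(payload, indent=1, sort_keys=True) + "\n")

print(f"selected {len(res.selected_features)} of {len(ds.feature_names)} "
      f"features (merit {res.merit:.3f}):")
for name in res.selected_features:
    print(" -", name)
print(f"wrote {RESULTS / 'selected_features.json'}")
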