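"""Population model: rotation forest under stratified cross-validation.

Evaluates the strong-coupling cohort in the study's own order of
operations (class-balancing resample of the full dataset before folding;
"replication") and in the leakage-free order (resampling and selection
inside training folds), each with all features and with the CFS subset,
plus the uncoupled control cohort. Writes
``results/population_eval.json``.
"""

import json

from _common import (EVAL_SEED, RESULTS, ensure_dirs, null_cohort,
                     strong_cohort)
from symburden.classify import ClassifierConfig, stratified_cv
from symburden.experiments import light_config, majority_rate
from symburden.pipeline import cohort_dataset

ensure_dirs()
ds, _, _ = cohort_dataset(strong_cohort())
out = {}
for mode in ("replication", "leakage_free"):
    for selector in ("none", "cfs-pearson"):
        cfg = ClassifierConfig()
        cfg.mode, cfg.selector = mode, selector
        rep = stratified_cv(ds, cfg, seed=EVAL_SEED)
        key = f"{mode}_{'all' if selector == 'none' else 'selected'}"
        out[key] = {"accuracy_pct": round(rep.accuracy, 1),
                    "n_days": rep.n_days}
        print(f"{key:28s} {rep.accuracy:5.1f}%")

nds, _, _ = cohort_dataset(null_cohort())
nrep = stratified_cv(nds, light_config(), seed=EVAL_SEED)
out["null_control"] = {
    "accuracy_pct": round(nrep.accuracy, 1),
    "majority_rate_pct": round(100 * majority_rate(nds.y), 1),
    "n_days": nrep.n_days}
print(f"{'null_control':28s} {nrep.accuracy:5.1f}% "
      f"(majority {out['null_control']['majority_rate_pct']}%)")

(RESULTS / "population_eval.json").write_text(
    json.dumps(out, indent=1, sort_keys=True) + "\n")
print(f"wrote {RESULTS / 'population_eval.json'}")
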