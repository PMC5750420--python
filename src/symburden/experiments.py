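"""The study's experiments, packaged as reusable drivers.

Each function generates (or accepts) a synthetic cohort, runs the
pipeline end to end and returns plain data structures; the numbered
analysis scripts, the test suite and the acceptance script all call
these rather than re-implementing the experiment logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (ClassifierConfig, EvalReport, leave_one_day_out_cv,
                       stratified_cv)
from .correlations import correlate_features
from .datatypes import LabeledDataset
from .pipeline import cohort_dataset
from .synthetic import (COUPLED_FEATURE_SIGNS, CohortConfig, generate_cohort,
                        low_preset, null_preset, strong_preset)


def light_config(**overrides) -> ClassifierConfig:
    """Reduced ensemble for simulation sweeps (3 members x 30 trees)."""
    cfg = ClassifierConfig().light()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def majority_rate(y: np.ndarray) -> float:
    return max(float(np.mean(y == c)) for c in set(int(v) for v in y))


def binomial_interval(p0: float, n: int) -> tuple[float, float]:
    hw = 1.96 * np.sqrt(p0 * (1.0 - p0) / n)
    return p0 - hw, p0 + hw


# ---------------------------------------------------------------------------
# null control


def null_control_experiment(n_cohorts: int = 20, n_patients: int = 10,
                            days: int = 30, cohort_seed_base: int = 100,
                            eval_seed_base: int = 200) -> pd.DataFrame:
    """Leakage-free CV accuracy on null-coupling cohorts vs the majority rate.

    One row per cohort: accuracy (%), majority rate (%), and whether the
    accuracy falls inside the 95% binomial interval around the majority
    rate — with no symptom→behavior coupling the classifier should do no
    better (or worse) than that baseline.
    """
    rows = []
    for i in range(n_cohorts):
        cohort = generate_cohort(null_preset(n_patients, days,
                                             seed=cohort_seed_base + i))
        ds, _, _ = cohort_dataset(cohort)
        rep = stratified_cv(ds, light_config(), seed=eval_seed_base + i)
        p0 = majority_rate(ds.y)
        lo, hi = binomial_interval(p0, len(ds))
        rows.append({"cohort_seed": cohort_seed_base + i,
                     "n_days": len(ds),
                     "accuracy_pct": rep.accuracy,
                     "majority_rate_pct": 100.0 * p0,
                     "inside_interval": lo <= rep.accuracy / 100.0 <= hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal recovery


@dataclass
class SignalRecoveryResult:
    n_days: int
    replication_all: EvalReport
    replication_selected: EvalReport
    leakage_free_all: EvalReport
    leakage_free_selected: EvalReport
    correlations: pd.DataFrame
    coupled_r: dict[str, float] = field(default_factory=dict)


def signal_recovery_experiment(n_patients: int = 10, days: int = 30,
                               cohort_seed: int = 3, eval_seed: int = 4,
                               config: ClassifierConfig | None = None
                               ) -> SignalRecoveryResult:
    """Population model on the strong-coupling preset.

    Runs the full default classifier in both evaluation modes, with and
    without CFS selection, and screens the designed coupled features'
    correlations with burden.
    """
    cohort = generate_cohort(strong_preset(n_patients, days, seed=cohort_seed))
    ds, _, _ = cohort_dataset(cohort)
    base = config or ClassifierConfig()
    reports = {}
    for mode in ("replication", "leakage_free"):
        for selector in ("none", "cfs-pearson"):
            cfg = ClassifierConfig(**vars(base))
            cfg.mode = mode
            cfg.selector = selector
            reports[(mode, selector)] = stratified_cv(ds, cfg, seed=eval_seed)
    corr = correlate_features(ds)
    coupled_r = {}
    for name in COUPLED_FEATURE_SIGNS:
        row = corr[corr["feature"] == name]
        if len(row):
            coupled_r[name] = float(row["r"].iloc[0])
    return SignalRecoveryResult(
        n_days=len(ds),
        replication_all=reports[("replication", "none")],
        replication_selected=reports[("replication", "cfs-pearson")],
        leakage_free_all=reports[("leakage_free", "none")],
        leakage_free_selected=reports[("leakage_free", "cfs-pearson")],
        correlations=corr, coupled_r=coupled_r)


# ---------------------------------------------------------------------------
# sign recovery


def sign_recovery_experiment(n_replicates: int = 20, n_patients: int = 6,
                             days: int = 15, seed_base: int = 500
                             ) -> pd.DataFrame:
    """Direction of every designed coupled correlation, per replicate.

    A replicate counts as correct when each coupled feature present in
    the cohort correlates with burden in the designed direction (e.g.
    step count negatively, sedentary-bout count positively).
    """
    rows = []
    for i in range(n_replicates):
        cohort = generate_cohort(
            strong_preset(n_patients, days, seed=seed_base + i))
        ds, _, _ = cohort_dataset(cohort)
        corr = correlate_features(ds).set_index("feature")
        ok, n_checked = True, 0
        for name, sign in COUPLED_FEATURE_SIGNS.items():
            if name not in corr.index:
                continue  # stream missing for the whole replicate cohort
            n_checked += 1
            if np.sign(corr.loc[name, "r"]) != sign:
                ok = False
        rows.append({"seed": seed_base + i, "n_days": len(ds),
                     "n_features_checked": n_checked, "all_signs_correct": ok})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coupling monotonicity


def coupling_curve(n_patients: int = 10, days: int = 30,
                   cohort_seed: int = 11, eval_seed: int = 12,
                   config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Population accuracy across the coupling grid {null, low, strong}."""
    cfg0 = config or light_config()
    rows = []
    for label, preset in (("null", null_preset), ("low", low_preset),
                          ("strong", strong_preset)):
        cohort = generate_cohort(preset(n_patients, days, seed=cohort_seed))
        ds, _, _ = cohort_dataset(cohort)
        rep = stratified_cv(ds, ClassifierConfig(**vars(cfg0)),
                            seed=eval_seed)
        rows.append({"coupling": label, "n_days": len(ds),
                     "accuracy_pct": rep.accuracy})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual models


def individual_models_experiment(ds: LabeledDataset,
                                 config: ClassifierConfig | None = None,
                                 seed: int = 0, min_days: int = 5
                                 ) -> dict[str, dict[str, EvalReport]]:
    """Leave-one-day-out models per patient, with and without selection.

    Patients with fewer than ``min_days`` labeled days or a single class
    are skipped (mirroring the cohort's own exclusion rules).
    """
    base = config or light_config()
    out: dict[str, dict[str, EvalReport]] = {}
    for pid in ds.patients:
        sub = ds.for_patient(pid)
        if len(sub) < min_days or len(set(int(v) for v in sub.y)) < 2:
            continue
        pair = {}
        for key, selector in (("all", "none"), ("selected", "cfs-pearson")):
            cfg = ClassifierConfig(**vars(base))
            cfg.selector = selector
            pair[key] = leave_one_day_out_cv(sub, cfg, seed=seed)
        out[pid] = pair
    return out
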