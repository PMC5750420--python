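"""End-to-end glue: raw streams → day windows → features → labels → dataset.

The labeled dataset keeps only patient-days that have *both* sensor and
symptom data, and drops days whose feature row is entirely missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LabeledDataset
from .features import (FEATURE_NAMES, assemble_feature_vector,
                       build_location_context, features_frame)
from .ingest import window_days
from .labels import build_labels
from .synthetic import Cohort


def extract_cohort_features(cohort: Cohort) -> pd.DataFrame:
    """Wide day-level feature frame for every patient-day of a cohort."""
    tz = cohort.config.timezone
    vectors = []
    for pid in sorted(cohort.patients):
        p = cohort.patients[pid]
        days = window_days(p.streams, pid, p.start_date, p.end_date, tz=tz)
        loc_ctx = build_location_context(days)
        for day in days:
            vectors.append(assemble_feature_vector(day, loc_ctx))
    return features_frame(vectors)


def build_dataset(features: pd.DataFrame, labels: pd.DataFrame) -> LabeledDataset:
    """Inner-join features and labels on (patient_id, date)."""
    merged = features.merge(labels, on=["patient_id", "date"], how="inner")
    X = merged[FEATURE_NAMES].astype(float)
    keep = ~X.isna().all(axis=1)
    merged = merged.loc[keep].reset_index(drop=True)
    X = X.loc[keep].reset_index(drop=True)
    return LabeledDataset(
        X=X,
        y=merged["klass"].to_numpy(int),
        keys=merged[["patient_id", "date"]].copy(),
        burden=merged["burden_score"].to_numpy(float))


def cohort_dataset(cohort: Cohort, epsilon: float = 0.0
                   ) -> tuple[LabeledDataset, pd.DataFrame, pd.DataFrame]:
    """Features, labels and the joined dataset for a cohort."""
    features = extract_cohort_features(cohort)
    labels = build_labels(cohort.symptoms, tz=cohort.config.timezone,
                          epsilon=epsilon)
    return build_dataset(features, labels), features, labels


# ---------------------------------------------------------------------------
# deterministic table output (same inputs => identical bytes)


def write_features_csv(features: pd.DataFrame, path: str | Path,
                       layout: str = "wide") -> None:
    df = features.sort_values(["patient_id", "date"], kind="stable")
    if layout == "long":
        df = df.melt(id_vars=["patient_id", "date"], var_name="feature",
                     value_name="value")
        df["missing"] = df["value"].isna().astype(int)
        df = df.sort_values(["patient_id", "date", "feature"], kind="stable")
    elif layout != "wide":
        raise ValueError("layout must be 'wide' or 'long'")
    _write_canonical(df, path)


def write_labels_csv(labels: pd.DataFrame, path: str | Path) -> None:
    _write_canonical(labels.sort_values(["patient_id", "date"], kind="stable"),
                     path)


def _write_canonical(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else "%.9g" % v)
    out.to_csv(path, index=False, lineterminator="\n")
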