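"""Daily symptom-burden composite and the per-patient 3-class label.

Patients rate 12 symptoms 0-10 up to twice a day. The daily composite is
the sum over symptoms of the per-symptom mean across that day's prompts
(range 0-120). Classes are assigned per patient by centering on the
patient's own mean: a day is low (−1), normal (0) or high (+1) depending
on whether its residual falls below, inside, or above a band of half-width
``epsilon`` around zero. With the default ``epsilon = 0`` the normal class
occurs only on exact ties with the mean (the literal rule); a positive
band makes the middle class non-degenerate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import SYMPTOMS, BurdenLabel


def daily_burden(ratings: pd.DataFrame) -> float:
    """Composite burden for one patient-day: sum of per-symptom prompt means.

    ``ratings`` holds that day's prompt records (morning/evening) with one
    column per symptom. Raises ``ValueError`` when no record exists — such
    days carry no label and are excluded upstream.
    """
    if ratings is None or len(ratings) == 0:
        raise ValueError("no symptom records for this day")
    return float(sum(ratings[s].astype(float).mean() for s in SYMPTOMS))


def classify_residual(residual: float, epsilon: float = 0.0) -> int:
    if residual < -epsilon:
        return -1
    if residual > epsilon:
        return 1
    return 0


def center_and_classify(burden: pd.Series, patient_id: str = "",
                        epsilon: float = 0.0) -> list[BurdenLabel]:
    """Center one patient's burden series on its mean and classify each day.

    Needs at least two labeled days (a single day cannot be centered; the
    patient is excluded with a warning upstream).
    """
    if len(burden) < 2:
        raise ValueError(
            f"patient {patient_id!r}: {len(burden)} labeled day(s); "
            "need >= 2 to center")
    mean = float(burden.mean())
    out = []
    for date, score in burden.items():
        resid = float(score) - mean
        out.append(BurdenLabel(
            patient_id=patient_id, date=date, burden_score=float(score),
            patient_mean=mean, residual=resid,
            klass=classify_residual(resid, epsilon)))
    return out


def build_labels(symptoms: pd.DataFrame, tz: str = "America/New_York",
                 epsilon: float = 0.0) -> pd.DataFrame:
    """Labels for a whole cohort from the raw symptom-rating stream.

    Returns a frame with columns patient_id, date, burden_score,
    patient_mean, residual, klass. Patients with fewer than two rated days
    are dropped with a warning.
    """
    df = symptoms.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["date"] = ts.dt.tz_convert(tz).dt.date
    # per-symptom mean over the day's prompts, summed over symptoms
    per_day_all = (df.groupby(["patient_id", "date"], sort=True)[list(SYMPTOMS)]
                   .mean().astype(float).sum(axis=1))
    rows = []
    for pid in per_day_all.index.get_level_values(0).unique():
        per_day = per_day_all.loc[pid]
        if len(per_day) < 2:
            warnings.warn(
                f"patient {pid!r} has {len(per_day)} rated day(s); excluded")
            continue
        rows.extend(center_and_classify(per_day, patient_id=pid, epsilon=epsilon))
    out = pd.DataFrame(
        [(r.patient_id, r.date, r.burden_score, r.patient_mean,
          r.residual, r.klass) for r in rows],
        columns=["patient_id", "date", "burden_score", "patient_mean",
                 "residual", "klass"])
    if len(out):
        resid_means = out.groupby("patient_id")["residual"].mean()
        assert np.all(np.abs(resid_means.to_numpy()) < 1e-9)
    return out
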