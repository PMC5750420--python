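"""Shared containers for the symptom-burden pipeline.

The unit of analysis throughout is the patient-day: all raw events of one
patient falling inside one midnight-to-midnight local-time window. A
:class:`SensorDay` holds those events grouped by stream; a day-level
:class:`FeatureVector` summarises them; a :class:`BurdenLabel` carries the
patient-reported side; a :class:`LabeledDataset` joins the two for the
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Any

import numpy as np
import pandas as pd

#: Sensor stream identifiers, in canonical order.
STREAMS: tuple[str, ...] = (
    "accel",
    "gps",
    "activity",
    "screen",
    "apps",
    "battery",
    "comm",
    "fitbit_minutes",
    "fitbit_daily",
    "fitbit_sleep",
)

ACTIVITY_VOCAB: tuple[str, ...] = (
    "in_vehicle",
    "on_bicycle",
    "on_foot",
    "still",
    "tilting",
    "unknown",
)

SCREEN_VOCAB: tuple[str, ...] = ("lock", "off", "on", "unlock")
APP_EVENT_VOCAB: tuple[str, ...] = ("foreground_end", "foreground_start")
BATTERY_VOCAB: tuple[str, ...] = ("charging_end", "charging_start")
COMM_CHANNELS: tuple[str, ...] = ("call", "sms")
COMM_DIRECTIONS: tuple[str, ...] = ("incoming", "missed", "outgoing")

#: The 12 symptoms rated twice daily on a 0-10 scale.
SYMPTOMS: tuple[str, ...] = (
    "pain",
    "fatigue",
    "disconnected",
    "concentration",
    "sad",
    "anxious",
    "anhedonia",
    "irritable",
    "dyspnea",
    "numbness",
    "nausea",
    "appetite",
)

CLASSES: tuple[int, ...] = (-1, 0, 1)


class SymburdenError(Exception):
    """Base class for package errors."""


class ConfigError(SymburdenError):
    """Invalid configuration value; message names the offending field."""


class FormatError(SymburdenError):
    """A stream file does not match its documented dialect."""


class IntegrityError(SymburdenError):
    """Too many malformed rows, or an impossible record."""


class RegistryError(SymburdenError, KeyError):
    """Unknown feature name."""


@dataclass
class SensorDay:
    """One patient's events in one [00:00, 24:00) local-time window.

    ``streams`` maps stream name to the day's point events; ``intervals``
    holds reconstructed sessions (screen, app, charge) already clipped to
    the window, so interval durations straddling midnight are apportioned.
    ``present`` is a per-stream flag: a stream the patient never recorded
    is absent (features missing), a recorded stream with no events that
    day is present-and-empty (counts are legitimate zeros).
    """

    patient_id: str
    date: Date
    streams: dict[str, pd.DataFrame] = field(default_factory=dict)
    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)
    present: dict[str, bool] = field(default_factory=dict)
    monitored_minutes: float = 1440.0

    def stream(self, name: str) -> pd.DataFrame:
        if name not in STREAMS:
            raise KeyError(f"unknown stream {name!r}")
        return self.streams.get(name, pd.DataFrame())

    def has(self, name: str) -> bool:
        return bool(self.present.get(name, False))


@dataclass
class FeatureVector:
    """Named day-level feature values with explicit missingness."""

    patient_id: str
    date: Date
    values: dict[str, Any] = field(default_factory=dict)

    def is_missing(self, name: str) -> bool:
        v = self.values.get(name)
        return v is None or (isinstance(v, float) and np.isnan(v))


@dataclass
class BurdenLabel:
    """Daily composite burden and its per-patient residual class."""

    patient_id: str
    date: Date
    burden_score: float
    patient_mean: float
    residual: float
    klass: int

    def __post_init__(self) -> None:
        assert self.klass in CLASSES


@dataclass
class LabeledDataset:
    """Feature matrix + class labels, one row per labeled patient-day.

    ``X`` is a wide float frame (NaN = missing) indexed like ``keys``,
    ``y`` the class vector in {-1, 0, 1}, ``keys`` a (patient_id, date)
    frame aligned row-wise with both.
    """

    X: pd.DataFrame
    y: np.ndarray
    keys: pd.DataFrame
    burden: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.keys):
            raise ValueError("X, y and keys must be aligned row-wise")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def subset_features(self, names: list[str]) -> "LabeledDataset":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise RegistryError(f"unknown feature name(s): {missing}")
        return LabeledDataset(
            self.X[names].copy(), self.y.copy(), self.keys.copy(),
            None if self.burden is None else self.burden.copy(),
        )

    def subset_rows(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.X.iloc[idx].reset_index(drop=True),
            self.y[idx],
            self.keys.iloc[idx].reset_index(drop=True),
            None if self.burden is None else self.burden[idx],
        )

    def for_patient(self, patient_id: str) -> "LabeledDataset":
        idx = np.flatnonzero((self.keys["patient_id"] == patient_id).to_numpy())
        return self.subset_rows(idx)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.keys["patient_id"]))
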