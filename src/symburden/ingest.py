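"""Reading, validating and day-windowing the raw sensor stream dialects.

Every stream is a comma-separated text file with a header row and ISO-8601
timestamps (timezone offset included). ``read_stream`` parses and validates
one file, dropping (and counting) malformed rows; ``window_days`` slices a
patient's streams into midnight-to-midnight local-time windows, splitting
reconstructed sessions (screen interaction, app foreground, battery charge)
at midnight so each side of the boundary is credited with its own share.

The day window is half-open, ``[00:00, 24:00)`` local patient time: an
event stamped exactly at midnight belongs to the day that begins there.
On daylight-saving transition days the window is 23 or 25 hours long and
``SensorDay.monitored_minutes`` reflects that.
"""

from __future__ import annotations

import warnings
from datetime import date as Date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .datatypes import (
    ACTIVITY_VOCAB,
    APP_EVENT_VOCAB,
    BATTERY_VOCAB,
    COMM_CHANNELS,
    COMM_DIRECTIONS,
    SCREEN_VOCAB,
    STREAMS,
    SYMPTOMS,
    FormatError,
    IntegrityError,
    SensorDay,
)

#: Column layout of each stream dialect (header order is fixed).
DIALECTS: dict[str, list[str]] = {
    "accel": ["timestamp", "x", "y", "z"],
    "gps": ["timestamp", "lat", "lon", "accuracy"],
    "activity": ["timestamp", "label"],
    "screen": ["timestamp", "state"],
    "apps": ["timestamp", "app_id", "event"],
    "battery": ["timestamp", "state"],
    "comm": ["timestamp", "channel", "direction", "correspondent_hash", "duration_s"],
    "fitbit_minutes": ["timestamp", "steps"],
    "fitbit_daily": ["date", "steps", "distance_m", "floors",
                     "min_light", "min_fair", "min_very"],
    "fitbit_sleep": ["date", "min_asleep", "min_awake", "n_awakenings", "min_in_bed"],
    "symptoms": ["patient_id", "timestamp", *SYMPTOMS],
}

_NUMERIC_COLS: dict[str, list[str]] = {
    "accel": ["x", "y", "z"],
    "gps": ["lat", "lon", "accuracy"],
    "comm": ["duration_s"],
    "fitbit_minutes": ["steps"],
    "fitbit_daily": ["steps", "distance_m", "floors", "min_light", "min_fair", "min_very"],
    "fitbit_sleep": ["min_asleep", "min_awake", "n_awakenings", "min_in_bed"],
    "symptoms": list(SYMPTOMS),
}

_VOCABS: dict[str, dict[str, tuple[str, ...]]] = {
    "activity": {"label": ACTIVITY_VOCAB},
    "screen": {"state": SCREEN_VOCAB},
    "apps": {"event": APP_EVENT_VOCAB},
    "battery": {"state": BATTERY_VOCAB},
    "comm": {"channel": COMM_CHANNELS, "direction": COMM_DIRECTIONS},
}

_DATE_KEYED = ("fitbit_daily", "fitbit_sleep")


def read_stream(path, kind: str, tz: str | None = None,
                max_malformed_frac: float = 0.05) -> pd.DataFrame:
    """Parse and validate one stream file.

    Returns the events sorted ascending in time, with the count of dropped
    malformed rows in ``df.attrs["n_dropped"]``. Raises :class:`FormatError`
    on an unknown header and :class:`IntegrityError` when more than
    ``max_malformed_frac`` of rows are malformed.
    """
    if kind not in DIALECTS:
        raise KeyError(f"unknown stream kind {kind!r}")
    cols = DIALECTS[kind]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != cols:
        raise FormatError(
            f"{path}: header {list(df.columns)} does not match "
            f"{kind} dialect {cols}")
    n_raw = len(df)
    bad = np.zeros(n_raw, dtype=bool)

    if "timestamp" in cols:
        ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True,
                            format="ISO8601")
        bad |= ts.isna().to_numpy()
        df = df.assign(timestamp=ts if tz is None else ts.dt.tz_convert(tz))
    if "date" in cols:
        d = pd.to_datetime(df["date"], errors="coerce", format="%Y-%m-%d")
        bad |= d.isna().to_numpy()
        df = df.assign(date=d.dt.date)

    for c in _NUMERIC_COLS.get(kind, []):
        v = pd.to_numeric(df[c].replace("", np.nan), errors="coerce")
        if kind == "gps" and c == "accuracy":
            df[c] = v  # optional column, NaN allowed
            continue
        bad |= v.isna().to_numpy()
        df[c] = v
    for c, vocab in _VOCABS.get(kind, {}).items():
        bad |= ~df[c].isin(vocab).to_numpy()

    # domain rules
    if kind == "gps":
        bad |= ~df["lat"].between(-90, 90).fillna(True).to_numpy()
        bad |= ~df["lon"].between(-180, 180).fillna(True).to_numpy()
    elif kind == "comm":
        bad |= (df["duration_s"] < 0).fillna(True).to_numpy()
        bad |= ((df["direction"] == "missed") & (df["channel"] != "call")).to_numpy()
    elif kind in ("fitbit_minutes", "fitbit_daily", "fitbit_sleep"):
        for c in _NUMERIC_COLS[kind]:
            bad |= (df[c] < 0).fillna(True).to_numpy()
    elif kind == "symptoms":
        for c in SYMPTOMS:
            bad |= ~df[c].between(0, 10).fillna(True).to_numpy()

    n_dropped = int(bad.sum())
    if n_raw and n_dropped / n_raw > max_malformed_frac:
        raise IntegrityError(
            f"{path}: {n_dropped}/{n_raw} malformed rows exceeds "
            f"{max_malformed_frac:.0%} threshold")
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} malformed row(s)")
    df = df.loc[~bad]
    sort_key = "timestamp" if "timestamp" in cols else "date"
    df = df.sort_values(sort_key, kind="stable").reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    return df


# canonical float formatting so that identical inputs give identical bytes
_FLOAT_FMT: dict[str, dict[str, str]] = {
    "accel": {"x": "%.5f", "y": "%.5f", "z": "%.5f"},
    "gps": {"lat": "%.6f", "lon": "%.6f", "accuracy": "%.1f"},
    "comm": {"duration_s": "%.0f"},
}


def write_stream(df: pd.DataFrame, path, kind: str) -> None:
    """Write events in the canonical dialect (inverse of :func:`read_stream`)."""
    cols = DIALECTS[kind]
    out = df.copy()
    if "timestamp" in cols:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).map(
            lambda t: t.isoformat())
    for c, fmt in _FLOAT_FMT.get(kind, {}).items():
        if c in out:
            out[c] = [("" if pd.isna(v) else fmt % v) for v in out[c]]
    for c in _NUMERIC_COLS.get(kind, []):
        if c not in _FLOAT_FMT.get(kind, {}) and c in out:
            out[c] = out[c].map(lambda v: "" if pd.isna(v)
                                else ("%g" % v if v % 1 else "%d" % v))
    out.to_csv(path, index=False, columns=cols, lineterminator="\n")


# ---------------------------------------------------------------------------
# session reconstruction


def screen_sessions(screen: pd.DataFrame) -> pd.DataFrame:
    """Interaction sessions: each ``unlock`` to the next ``lock``/``off``.

    An unlock with no closing event is closed at the earlier of the next
    unlock or the end of its day (logs commonly truncate; the error is
    bounded by one day).
    """
    rows = []
    open_start = None
    for t, state in zip(screen["timestamp"], screen["state"]):
        if state == "unlock":
            if open_start is not None:
                rows.append((open_start, min(t, _day_end(open_start))))
            open_start = t
        elif state in ("lock", "off") and open_start is not None:
            rows.append((open_start, max(t, open_start)))
            open_start = None
    if open_start is not None:
        rows.append((open_start, _day_end(open_start)))
    return pd.DataFrame(rows, columns=["start", "end"])


def app_sessions(apps: pd.DataFrame) -> pd.DataFrame:
    """Foreground app sessions with truncation repair.

    An open session closes at the earliest of its own ``foreground_end``,
    the next ``foreground_start`` of any app (only one app is foreground
    at a time), or the end of its day.
    """
    rows = []
    cur_app, cur_start = None, None
    for t, app, ev in zip(apps["timestamp"], apps["app_id"], apps["event"]):
        if ev == "foreground_start":
            if cur_app is not None:
                rows.append((cur_start, min(t, _day_end(cur_start)), cur_app))
            cur_app, cur_start = app, t
        else:  # foreground_end
            if cur_app is not None and app == cur_app:
                rows.append((cur_start, max(t, cur_start), cur_app))
                cur_app, cur_start = None, None
    if cur_app is not None:
        rows.append((cur_start, _day_end(cur_start), cur_app))
    return pd.DataFrame(rows, columns=["start", "end", "app_id"])


def charge_sessions(battery: pd.DataFrame) -> pd.DataFrame:
    """Charging episodes from alternating start/end events (repaired)."""
    rows = []
    open_start = None
    for t, state in zip(battery["timestamp"], battery["state"]):
        if state == "charging_start":
            if open_start is None:  # duplicate starts: keep the first
                open_start = t
        elif open_start is not None:
            rows.append((open_start, max(t, open_start)))
            open_start = None
    if open_start is not None:
        rows.append((open_start, _day_end(open_start)))
    return pd.DataFrame(rows, columns=["start", "end"])


def _day_end(t: pd.Timestamp) -> pd.Timestamp:
    return (t.normalize() + timedelta(days=1))


def split_intervals_at_midnight(iv: pd.DataFrame, tz: str) -> pd.DataFrame:
    """Split [start, end) intervals at local midnights; adds a ``date`` column.

    The per-day pieces conserve total duration (to the clock's resolution).
    """
    if iv.empty:
        out = iv.copy()
        out["date"] = pd.Series(dtype=object)
        out["duration_min"] = pd.Series(dtype=float)
        return out
    extra = [c for c in iv.columns if c not in ("start", "end")]
    s = pd.DatetimeIndex(iv["start"]).tz_convert(tz)
    e = pd.DatetimeIndex(iv["end"]).tz_convert(tz)
    next_mid = s.normalize() + pd.Timedelta(days=1)
    simple = e <= next_mid  # common case: interval inside one day
    out = iv.loc[simple].copy()
    out["start"], out["end"] = s[simple], e[simple]
    out["date"] = s[simple].date
    pieces = []
    for i in np.flatnonzero(~simple):
        si, ei = s[i], e[i]
        ex = [iv.iloc[i][c] for c in extra]
        while si < ei:
            boundary = min(ei, si.normalize() + timedelta(days=1))
            pieces.append((si, boundary, *ex, si.date()))
            si = boundary
    if pieces:
        out = pd.concat(
            [out, pd.DataFrame(pieces, columns=["start", "end", *extra, "date"])],
            ignore_index=True)
    out = out.sort_values("start", kind="stable").reset_index(drop=True)
    out["duration_min"] = (
        pd.DatetimeIndex(out["end"]).asi8 - pd.DatetimeIndex(out["start"]).asi8
    ) / 60e9
    return out


# ---------------------------------------------------------------------------
# day windowing


def window_days(streams: dict[str, pd.DataFrame], patient_id: str,
                start_date: Date, end_date: Date,
                tz: str = "America/New_York") -> list[SensorDay]:
    """Slice a patient's streams into SensorDays covering [start, end] dates.

    ``streams`` maps stream name → events (absent key = stream never
    recorded). Point events are assigned by the half-open midnight rule;
    session intervals are rebuilt from the full stream first and split at
    midnight so durations are apportioned to each side.
    """
    present = {s: (s in streams) for s in STREAMS}
    local: dict[str, pd.DataFrame] = {}
    for name, df in streams.items():
        if name in _DATE_KEYED or df.empty or "timestamp" not in df.columns:
            local[name] = df
        else:
            d = df.copy()
            d["timestamp"] = pd.to_datetime(d["timestamp"], utc=True).dt.tz_convert(tz)
            local[name] = d.sort_values("timestamp", kind="stable")

    sessions = {
        "screen_sessions": split_intervals_at_midnight(
            screen_sessions(local["screen"]), tz) if present["screen"] else None,
        "app_sessions": split_intervals_at_midnight(
            app_sessions(local["apps"]), tz) if present["apps"] else None,
        "charge_sessions": split_intervals_at_midnight(
            charge_sessions(local["battery"]), tz) if present["battery"] else None,
    }

    # pre-group every stream by local date once (the half-open midnight
    # rule is exactly "same local calendar date")
    grouped: dict[str, dict[Date, pd.DataFrame]] = {}
    for name in STREAMS:
        if not present[name]:
            continue
        df = local[name]
        if df.empty:
            grouped[name] = {}
        elif name in _DATE_KEYED:
            grouped[name] = {d: g.reset_index(drop=True)
                             for d, g in df.groupby("date", sort=False)}
        else:
            # normalize() avoids boxing every timestamp into a date object
            key = df["timestamp"].dt.normalize()
            grouped[name] = {k.date(): g.reset_index(drop=True)
                             for k, g in df.groupby(key, sort=False)}

    days = []
    n_days = (end_date - start_date).days + 1
    for i in range(n_days):
        date = start_date + timedelta(days=i)
        t0 = pd.Timestamp(datetime.combine(date, datetime.min.time()), tz=tz)
        t1 = pd.Timestamp(datetime.combine(date + timedelta(days=1),
                                           datetime.min.time()), tz=tz)
        day_streams = {}
        for name in STREAMS:
            if not present[name]:
                continue
            empty = local[name].iloc[0:0]
            day_streams[name] = grouped[name].get(date, empty)
        intervals = {}
        for key, iv in sessions.items():
            if iv is not None:
                intervals[key] = (iv[iv["date"] == date].reset_index(drop=True)
                                  if not iv.empty else iv)
        days.append(SensorDay(
            patient_id=patient_id, date=date,
            streams=day_streams, intervals=intervals, present=present,
            monitored_minutes=(t1 - t0).total_seconds() / 60.0))
    return days
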