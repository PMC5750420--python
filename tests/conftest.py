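"""Shared fixtures: a hand-enumerable one-day recording and tiny cohorts."""

from datetime import date

import pandas as pd
import pytest

from symburden.ingest import window_days

TZ = "America/New_York"
DAY = date(2016, 2, 15)


def _t(hhmm: str, day: date = DAY) -> str:
    return f"{day.isoformat()}T{hhmm}:00-05:00"


def ts(items):
    return pd.to_datetime(items, utc=True).tz_convert(TZ)


@pytest.fixture(scope="session")
def fixture_streams() -> dict:
    """Raw streams for one hand-checkable day (all streams present)."""
    accel = pd.DataFrame({
        "timestamp": ts([_t("00:01"), _t("00:02"), _t("00:03"), _t("00:04")]),
        "x": [1.0, 0.0, 0.0, 0.0],
        "y": [0.0, 2.0, 0.0, 2.4],
        "z": [0.0, 0.0, 3.0, 3.2],
    })  # magnitudes 1, 2, 3, 4
    # two clumps of 6 fixes, ~5 km apart, 10-min spacing
    north = 40.0 + 0.0449661   # ~5000 m north of 40.0
    gps = pd.DataFrame({
        "timestamp": ts([_t(f"09:{m:02d}") for m in range(0, 60, 10)]
                        + [_t(f"14:{m:02d}") for m in range(0, 60, 10)]),
        "lat": [40.0] * 6 + [north] * 6,
        "lon": [-80.0] * 12,
        "accuracy": [10.0] * 12,
    })
    activity = pd.DataFrame({
        "timestamp": ts([_t("10:00"), _t("10:01"), _t("10:02"), _t("10:03")]),
        "label": ["still", "still", "on_foot", "still"],
    })
    screen = pd.DataFrame({
        "timestamp": ts([_t("10:00"), _t("10:30"), _t("12:00"), _t("12:10")]),
        "state": ["unlock", "lock", "unlock", "off"],
    })
    apps = pd.DataFrame({
        "timestamp": ts([_t("10:00"), _t("10:05"), _t("10:05"), _t("10:08"),
                         _t("10:08"), _t("10:10")]),
        "app_id": ["appA", "appA", "appB", "appB", "appA", "appA"],
        "event": ["foreground_start", "foreground_end"] * 3,
    })
    battery = pd.DataFrame({
        "timestamp": ts([_t("22:00"), _t("23:00")]),
        "state": ["charging_start", "charging_end"],
    })
    comm = pd.DataFrame({
        "timestamp": ts([_t("11:00"), _t("11:30"), _t("13:00"), _t("15:00")]),
        "channel": ["call", "call", "call", "sms"],
        "direction": ["incoming", "incoming", "missed", "outgoing"],
        "correspondent_hash": ["h1", "h1", "h2", "h3"],
        "duration_s": [60.0, 30.0, 0.0, 0.0],
    })
    fitbit_minutes = pd.DataFrame({
        "timestamp": ts([_t(f"08:{m:02d}") for m in range(9)]),
        "steps": [0, 0, 7, 0, 0, 0, 12, 5, 0],
    })
    fitbit_daily = pd.DataFrame({
        "date": [DAY], "steps": [24], "distance_m": [18.0], "floors": [1],
        "min_light": [3], "min_fair": [0], "min_very": [0],
    })
    fitbit_sleep = pd.DataFrame({
        "date": [DAY], "min_asleep": [420], "min_awake": [30],
        "n_awakenings": [3], "min_in_bed": [455],
    })
    return {
        "accel": accel, "gps": gps, "activity": activity, "screen": screen,
        "apps": apps, "battery": battery, "comm": comm,
        "fitbit_minutes": fitbit_minutes, "fitbit_daily": fitbit_daily,
        "fitbit_sleep": fitbit_sleep,
    }


@pytest.fixture(scope="session")
def fixture_day(fixture_streams):
    days = window_days(fixture_streams, "P01", DAY, DAY, tz=TZ)
    assert len(days) == 1
    return days[0]
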