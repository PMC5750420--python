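"""Day-level behavioral features from phone and wearable streams.

Each operation summarises one stream of a :class:`~symburden.datatypes.SensorDay`
into named features; :func:`assemble_feature_vector` combines them all. A
feature is *missing* (``NaN``) iff its source stream is absent for the
patient, its inputs are insufficient (e.g. a standard deviation from one
sample), or its denominator is zero — never silently zero-filled.

Location features follow the standard mobility-literature definitions:
location entropy is the Shannon entropy (natural log) of the day's
dwell-time distribution over clusters, and the radius of gyration is the
dwell-weighted RMS great-circle distance of cluster centroids from their
dwell-weighted centre.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .datatypes import ACTIVITY_VOCAB, FeatureVector, RegistryError, SensorDay

EARTH_RADIUS_M = 6_371_000.0
#: DBSCAN defaults: 100 m neighbourhood, 5 fixes to seed a cluster.
DEFAULT_EPS_M = 100.0
DEFAULT_MIN_SAMPLES = 5
#: Per-fix dwell is the gap to the next fix, capped (fused location emits
#: sparsely when stationary, so uncapped gaps overweight last fixes).
DWELL_CAP_MIN = 30.0

NA = float("nan")


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters (vectorised over array inputs)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# feature registry


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str   # Table-2 style category
    source: str     # sensor source, used by device/category ablations
    kind: str = "numeric"   # numeric | categorical


_R: list[FeatureSpec] = []


def _reg(names: Iterable[str], category: str, source: str, kind="numeric"):
    for n in names:
        _R.append(FeatureSpec(n, category, source, kind))


_reg(["n_activities", "most_common_activity", "n_activity_changes"],
     "Mobility and activity", "phone_activity")
_reg(["accel_min", "accel_max", "accel_mean", "accel_median", "accel_sd"],
     "Mobility and activity", "phone_accel")
_reg(["n_unique_locations", "time_in_most_frequent", "location_entropy",
      "radius_of_gyration", "travel_distance"],
     "Mobility and activity", "phone_gps")
_reg(["steps", "distance_m", "floors", "min_light", "min_fair", "min_very",
      "max_steps_per_min",
      "n_sedentary_bouts", "sedentary_bout_min_len", "sedentary_bout_max_len",
      "sedentary_bout_mean_len",
      "n_active_bouts", "active_bout_min_len", "active_bout_max_len",
      "active_bout_mean_len", "active_bout_max_steps", "active_bout_mean_steps"],
     "Mobility and activity", "fitbit_activity")
_reg(["min_asleep", "min_awake", "n_awakenings", "min_in_bed"],
     "Sleep", "fitbit_sleep")
_reg(["app_use_time", "apps_per_min", "n_unique_apps", "n_app_changes",
      "unlocks_per_min", "interaction_duration", "charge_duration"],
     "Phone usage", "phone_usage")
_reg(["n_in_calls", "dur_in_calls", "n_out_calls", "dur_out_calls",
      "n_missed_calls", "n_in_sms", "n_out_sms", "n_unique_correspondents",
      "most_frequent_contact"],
     "Communication", "phone_comm")

FEATURE_REGISTRY: dict[str, FeatureSpec] = {f.name: f for f in _R}
FEATURE_NAMES: list[str] = [f.name for f in _R]

# most_common_activity / most_frequent_contact are categorical at extraction
# time and integer-encoded when a numeric matrix is assembled
CATEGORICAL_FEATURES = ("most_common_activity", "most_frequent_contact")

#: Device / category groups for the ablation grid. "activity" bundles the
#: activity-recognition and phone-accelerometer features, "movement" adds
#: location, "phone" is everything phone-derived, "fitbit" everything from
#: the wearable (activity + sleep).
SOURCE_GROUPS: dict[str, tuple[str, ...]] = {
    "activity": ("phone_activity", "phone_accel"),
    "location": ("phone_gps",),
    "movement": ("phone_activity", "phone_accel", "phone_gps"),
    "phone_usage": ("phone_usage",),
    "communication": ("phone_comm",),
    "phone": ("phone_activity", "phone_accel", "phone_gps",
              "phone_usage", "phone_comm"),
    "fitbit": ("fitbit_activity", "fitbit_sleep"),
}


def feature_group(group: str) -> list[str]:
    """Feature names belonging to a named device/category group."""
    if group == "all":
        return list(FEATURE_NAMES)
    if group not in SOURCE_GROUPS:
        raise RegistryError(f"unknown feature group {group!r}")
    srcs = SOURCE_GROUPS[group]
    return [f.name for f in _R if f.source in srcs]


def registry_frame() -> pd.DataFrame:
    """The feature registry as a machine-readable table."""
    return pd.DataFrame([vars(f) for f in _R])


def encode_categorical(name: str, value) -> float:
    """Stable integer code for a categorical feature value."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return NA
    if name == "most_common_activity":
        return float(ACTIVITY_VOCAB.index(value))
    if name == "most_frequent_contact":
        return float(zlib.crc32(str(value).encode()) % 1009)
    raise RegistryError(f"{name} is not a categorical feature")


# ---------------------------------------------------------------------------
# accelerometer


def accel_magnitude_features(samples: pd.DataFrame) -> dict[str, float]:
    """Summary statistics of per-sample acceleration magnitude (m/s²).

    The standard deviation uses the sample (n−1) convention and needs at
    least two samples; with an empty input all five are missing.
    """
    if samples is None or len(samples) == 0:
        return dict.fromkeys(
            ("accel_min", "accel_max", "accel_mean", "accel_median", "accel_sd"), NA)
    mag = np.sqrt(samples["x"].to_numpy(float) ** 2
                  + samples["y"].to_numpy(float) ** 2
                  + samples["z"].to_numpy(float) ** 2)
    return {
        "accel_min": float(mag.min()),
        "accel_max": float(mag.max()),
        "accel_mean": float(mag.mean()),
        "accel_median": float(np.median(mag)),
        "accel_sd": float(np.std(mag, ddof=1)) if len(mag) >= 2 else NA,
    }


# ---------------------------------------------------------------------------
# activity recognition


def activity_features(events: pd.DataFrame) -> dict[str, object]:
    """Distinct-label count, modal activity and label-change count.

    "Number of activities" is interpreted as the number of distinct
    activity labels observed during the day (the raw event count is a
    sampling-cadence artifact). Modal-activity ties break to the
    lexicographically smallest label.
    """
    if events is None or len(events) == 0:
        return {"n_activities": NA, "most_common_activity": NA,
                "n_activity_changes": NA}
    labels = events["label"].to_list()
    counts = pd.Series(labels).value_counts()
    top = counts.max()
    most_common = sorted(counts[counts == top].index)[0]
    changes = sum(a != b for a, b in zip(labels, labels[1:]))
    return {"n_activities": float(counts.size),
            "most_common_activity": most_common,
            "n_activity_changes": float(changes)}


# ---------------------------------------------------------------------------
# location


@dataclass
class LocationCluster:
    cluster_id: int
    centroid: tuple[float, float]
    dwell_min: float
    n_fixes: int


@dataclass
class GlobalLocation:
    global_id: int
    centroid: tuple[float, float]
    total_dwell_min: float = 0.0


def _fix_dwell_minutes(fixes: pd.DataFrame, cap_min: float = DWELL_CAP_MIN,
                       day_end=None) -> np.ndarray:
    """Dwell credited to each fix: min(gap to next fix, cap)."""
    t = pd.DatetimeIndex(fixes["timestamp"]).asi8  # ns since epoch
    gaps = np.empty(len(t))
    if len(t) > 1:
        gaps[:-1] = (t[1:] - t[:-1]) / 60e9
    last = cap_min
    if day_end is not None:
        last = max(0.0, (pd.Timestamp(day_end).value - t[-1]) / 60e9)
    gaps[-1] = last
    return np.minimum(gaps, cap_min)


def cluster_day_locations(fixes: pd.DataFrame, eps_m: float = DEFAULT_EPS_M,
                          min_samples: int = DEFAULT_MIN_SAMPLES,
                          day_end=None) -> tuple[list[LocationCluster], np.ndarray]:
    """Density clusters of a day's GPS fixes over great-circle distance.

    Returns the clusters and the per-fix assignment vector (−1 = noise).
    Fewer than ``min_samples`` fixes yield no clusters.
    """
    if fixes is None or len(fixes) == 0:
        return [], np.empty(0, dtype=int)
    coords = np.radians(fixes[["lat", "lon"]].to_numpy(float))
    if len(fixes) < min_samples:
        return [], np.full(len(fixes), -1)
    labels = DBSCAN(eps=eps_m / EARTH_RADIUS_M, min_samples=min_samples,
                    metric="haversine").fit_predict(coords)
    dwell = _fix_dwell_minutes(fixes, day_end=day_end)
    clusters = []
    for cid in sorted(set(labels) - {-1}):
        m = labels == cid
        clusters.append(LocationCluster(
            cluster_id=int(cid),
            centroid=(float(fixes["lat"].to_numpy(float)[m].mean()),
                      float(fixes["lon"].to_numpy(float)[m].mean())),
            dwell_min=float(dwell[m].sum()),
            n_fixes=int(m.sum())))
    return clusters, labels


def match_global_locations(
        clusters_by_day: Mapping[object, list[LocationCluster]],
        merge_radius_m: float = DEFAULT_EPS_M,
) -> tuple[list[GlobalLocation], dict[tuple[object, int], int]]:
    """Merge per-day clusters into recurring global locations.

    Days are processed chronologically; a day cluster joins the nearest
    existing global location within the merge radius (dwell-weighted
    running centroid) or founds a new one.
    """
    globals_: list[GlobalLocation] = []
    mapping: dict[tuple[object, int], int] = {}
    for date in sorted(clusters_by_day):
        for cl in sorted(clusters_by_day[date], key=lambda c: -c.dwell_min):
            best, best_d = None, np.inf
            for g in globals_:
                d = float(haversine_m(cl.centroid[0], cl.centroid[1],
                                      g.centroid[0], g.centroid[1]))
                if d < best_d:
                    best, best_d = g, d
            if best is not None and best_d <= merge_radius_m:
                w = best.total_dwell_min + cl.dwell_min
                if w > 0:
                    best.centroid = (
                        (best.centroid[0] * best.total_dwell_min
                         + cl.centroid[0] * cl.dwell_min) / w,
                        (best.centroid[1] * best.total_dwell_min
                         + cl.centroid[1] * cl.dwell_min) / w)
                best.total_dwell_min = w
                mapping[(date, cl.cluster_id)] = best.global_id
            else:
                g = GlobalLocation(global_id=len(globals_),
                                   centroid=cl.centroid,
                                   total_dwell_min=cl.dwell_min)
                globals_.append(g)
                mapping[(date, cl.cluster_id)] = g.global_id
    return globals_, mapping


def location_features(day_clusters: list[LocationCluster], fixes: pd.DataFrame,
                      global_map: dict[tuple[object, int], int] | None = None,
                      globals_: list[GlobalLocation] | None = None,
                      date=None, top_mode: str = "global") -> dict[str, float]:
    """GPS mobility summary for one day.

    ``time_in_most_frequent`` defaults to today's dwell at the patient's
    overall most-visited global location (0 when clustered but unvisited);
    ``top_mode="day"`` uses the day's own top cluster instead. Travel
    distance is computable from two fixes even when no cluster forms.
    """
    out = dict.fromkeys(("n_unique_locations", "time_in_most_frequent",
                         "location_entropy", "radius_of_gyration",
                         "travel_distance"), NA)
    if fixes is not None and len(fixes) >= 2:
        lat = fixes["lat"].to_numpy(float)
        lon = fixes["lon"].to_numpy(float)
        out["travel_distance"] = float(
            haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum())
    if not day_clusters:
        return out
    dwell = np.array([c.dwell_min for c in day_clusters], dtype=float)
    out["n_unique_locations"] = float(len(day_clusters))
    total = dwell.sum()
    if total > 0:
        p = dwell / total
        nz = p[p > 0]
        out["location_entropy"] = float(-(nz * np.log(nz)).sum())
        lats = np.array([c.centroid[0] for c in day_clusters])
        lons = np.array([c.centroid[1] for c in day_clusters])
        clat, clon = float((p * lats).sum()), float((p * lons).sum())
        d = haversine_m(lats, lons, clat, clon)
        out["radius_of_gyration"] = float(np.sqrt((p * d ** 2).sum()))
    if top_mode == "day" or global_map is None or globals_ is None:
        out["time_in_most_frequent"] = float(dwell.max())
    else:
        top = max(globals_, key=lambda g: (g.total_dwell_min, -g.global_id))
        today = sum(c.dwell_min for c in day_clusters
                    if global_map.get((date, c.cluster_id)) == top.global_id)
        out["time_in_most_frequent"] = float(today)
    return out


# ---------------------------------------------------------------------------
# Fitbit minute-level bouts


@dataclass
class Bout:
    kind: str           # "sedentary" | "active"
    start_minute: pd.Timestamp
    length: int         # minutes
    total_steps: int    # 0 iff sedentary


def detect_bouts(minutes: pd.DataFrame) -> list[Bout]:
    """Maximal runs of zero-step vs ≥1-step minutes; coverage gaps break runs."""
    if minutes is None or len(minutes) == 0:
        return []
    t = pd.to_datetime(minutes["timestamp"]).reset_index(drop=True)
    tv = pd.DatetimeIndex(t).asi8
    steps = minutes["steps"].to_numpy(int)
    n = len(steps)
    if n == 1:
        breaks = np.array([], dtype=int)
    else:
        gap = (tv[1:] - tv[:-1]) > 60e9
        change = (steps[1:] > 0) != (steps[:-1] > 0)
        breaks = np.flatnonzero(gap | change) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    csum = np.concatenate(([0], np.cumsum(steps)))
    return [Bout(kind="active" if steps[s] > 0 else "sedentary",
                 start_minute=t[s], length=int(e - s),
                 total_steps=int(csum[e] - csum[s]))
            for s, e in zip(starts, ends)]


def fitbit_activity_features(summary: pd.DataFrame | None,
                             minutes: pd.DataFrame | None) -> dict[str, float]:
    """Daily summary pass-through plus minute-level bout structure.

    Minute-derived features are missing when raw minute data is absent
    (common in practice when the cloud export fails for a patient).
    """
    out = dict.fromkeys(
        ("steps", "distance_m", "floors", "min_light", "min_fair", "min_very",
         "max_steps_per_min",
         "n_sedentary_bouts", "sedentary_bout_min_len", "sedentary_bout_max_len",
         "sedentary_bout_mean_len",
         "n_active_bouts", "active_bout_min_len", "active_bout_max_len",
         "active_bout_mean_len", "active_bout_max_steps",
         "active_bout_mean_steps"), NA)
    if summary is not None and len(summary) > 0:
        row = summary.iloc[0]
        for src, dst in (("steps", "steps"), ("distance_m", "distance_m"),
                         ("floors", "floors"), ("min_light", "min_light"),
                         ("min_fair", "min_fair"), ("min_very", "min_very")):
            out[dst] = float(row[src])
    if minutes is not None and len(minutes) > 0:
        out["max_steps_per_min"] = float(minutes["steps"].max())
        bouts = detect_bouts(minutes)
        sed = [b.length for b in bouts if b.kind == "sedentary"]
        act = [b for b in bouts if b.kind == "active"]
        out["n_sedentary_bouts"] = float(len(sed))
        if sed:
            out["sedentary_bout_min_len"] = float(min(sed))
            out["sedentary_bout_max_len"] = float(max(sed))
            out["sedentary_bout_mean_len"] = float(np.mean(sed))
        out["n_active_bouts"] = float(len(act))
        if act:
            lens = [b.length for b in act]
            stp = [b.total_steps for b in act]
            out["active_bout_min_len"] = float(min(lens))
            out["active_bout_max_len"] = float(max(lens))
            out["active_bout_mean_len"] = float(np.mean(lens))
            out["active_bout_max_steps"] = float(max(stp))
            out["active_bout_mean_steps"] = float(np.mean(stp))
    return out


# ---------------------------------------------------------------------------
# sleep


def sleep_features(sleep: pd.DataFrame | None) -> dict[str, float]:
    """Fitbit nightly summary pass-through (sleep attributed to the morning)."""
    out = dict.fromkeys(("min_asleep", "min_awake", "n_awakenings",
                         "min_in_bed"), NA)
    if sleep is None or len(sleep) == 0:
        return out
    row = sleep.iloc[0]
    if row["min_asleep"] + row["min_awake"] > row["min_in_bed"] + 1:
        import warnings
        warnings.warn("sleep record exceeds time in bed by more than 1 min; kept")
    for c in out:
        out[c] = float(row[c])
    return out


# ---------------------------------------------------------------------------
# phone usage


def phone_usage_features(day: SensorDay) -> dict[str, float]:
    """Screen-interaction, app and battery-charge durations for one day.

    Rates divide by the day's monitored minutes (1440 except on DST or
    partial days). Sessions were split at midnight upstream, so durations
    here are already the day's own share.
    """
    out = dict.fromkeys(("app_use_time", "apps_per_min", "n_unique_apps",
                         "n_app_changes", "unlocks_per_min",
                         "interaction_duration", "charge_duration"), NA)
    mins = day.monitored_minutes
    if day.has("screen"):
        sess = day.intervals.get("screen_sessions")
        dur = 0.0 if sess is None or sess.empty else float(sess["duration_min"].sum())
        out["interaction_duration"] = dur
        ev = day.stream("screen")
        n_unlocks = 0 if ev.empty else int((ev["state"] == "unlock").sum())
        out["unlocks_per_min"] = n_unlocks / mins if mins > 0 else NA
    if day.has("apps"):
        sess = day.intervals.get("app_sessions")
        if sess is None or sess.empty:
            out.update(app_use_time=0.0, n_unique_apps=0.0, n_app_changes=0.0,
                       apps_per_min=0.0 if mins > 0 else NA)
        else:
            out["app_use_time"] = float(sess["duration_min"].sum())
            out["n_unique_apps"] = float(sess["app_id"].nunique())
            apps = sess.sort_values("start")["app_id"].to_list()
            out["n_app_changes"] = float(
                sum(a != b for a, b in zip(apps, apps[1:])))
            out["apps_per_min"] = len(sess) / mins if mins > 0 else NA
    if day.has("battery"):
        sess = day.intervals.get("charge_sessions")
        out["charge_duration"] = (0.0 if sess is None or sess.empty
                                  else float(sess["duration_min"].sum()))
    return out


# ---------------------------------------------------------------------------
# communication


def communication_features(comm: pd.DataFrame | None) -> dict[str, object]:
    """Call/SMS counts and durations from the hashed communication log.

    With the stream present but empty, counts are true zeros and the modal
    correspondent is missing; ties break to the lexicographically smallest
    hash.
    """
    if comm is None:
        return dict.fromkeys(
            ("n_in_calls", "dur_in_calls", "n_out_calls", "dur_out_calls",
             "n_missed_calls", "n_in_sms", "n_out_sms",
             "n_unique_correspondents", "most_frequent_contact"), NA)
    call = comm["channel"] == "call" if len(comm) else pd.Series(dtype=bool)
    sms = comm["channel"] == "sms" if len(comm) else pd.Series(dtype=bool)
    out: dict[str, object] = {
        "n_in_calls": 0.0, "dur_in_calls": 0.0, "n_out_calls": 0.0,
        "dur_out_calls": 0.0, "n_missed_calls": 0.0, "n_in_sms": 0.0,
        "n_out_sms": 0.0, "n_unique_correspondents": 0.0,
        "most_frequent_contact": NA,
    }
    if len(comm) == 0:
        return out
    inc = comm["direction"] == "incoming"
    outg = comm["direction"] == "outgoing"
    out["n_in_calls"] = float((call & inc).sum())
    out["dur_in_calls"] = float(comm.loc[call & inc, "duration_s"].sum())
    out["n_out_calls"] = float((call & outg).sum())
    out["dur_out_calls"] = float(comm.loc[call & outg, "duration_s"].sum())
    out["n_missed_calls"] = float((comm["direction"] == "missed").sum())
    out["n_in_sms"] = float((sms & inc).sum())
    out["n_out_sms"] = float((sms & outg).sum())
    counts = comm["correspondent_hash"].value_counts()
    out["n_unique_correspondents"] = float(counts.size)
    top = counts.max()
    out["most_frequent_contact"] = sorted(counts[counts == top].index)[0]
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class LocationContext:
    """Patient-level clustering context shared across that patient's days."""
    clusters_by_day: dict[object, list[LocationCluster]]
    globals_: list[GlobalLocation]
    global_map: dict[tuple[object, int], int]


def build_location_context(days: list[SensorDay],
                           eps_m: float = DEFAULT_EPS_M,
                           min_samples: int = DEFAULT_MIN_SAMPLES) -> LocationContext:
    """Cluster every day's fixes, then merge across days into globals."""
    by_day: dict[object, list[LocationCluster]] = {}
    for day in days:
        if day.has("gps"):
            clusters, _ = cluster_day_locations(
                day.stream("gps"), eps_m=eps_m, min_samples=min_samples)
            by_day[day.date] = clusters
    globals_, mapping = match_global_locations(by_day, merge_radius_m=eps_m)
    return LocationContext(by_day, globals_, mapping)


def assemble_feature_vector(day: SensorDay,
                            loc_ctx: LocationContext | None = None,
                            top_mode: str = "global") -> FeatureVector:
    """All registry features for one day, each present as value-or-missing."""
    values: dict[str, object] = dict.fromkeys(FEATURE_NAMES, NA)

    if day.has("accel"):
        values.update(accel_magnitude_features(day.stream("accel")))
    if day.has("activity"):
        values.update(activity_features(day.stream("activity")))
    if day.has("gps"):
        if loc_ctx is not None and day.date in loc_ctx.clusters_by_day:
            clusters = loc_ctx.clusters_by_day[day.date]
        else:
            clusters, _ = cluster_day_locations(day.stream("gps"))
        values.update(location_features(
            clusters, day.stream("gps"),
            loc_ctx.global_map if loc_ctx else None,
            loc_ctx.globals_ if loc_ctx else None,
            date=day.date, top_mode=top_mode))
    if day.has("fitbit_daily") or day.has("fitbit_minutes"):
        values.update(fitbit_activity_features(
            day.stream("fitbit_daily") if day.has("fitbit_daily") else None,
            day.stream("fitbit_minutes") if day.has("fitbit_minutes") else None))
    if day.has("fitbit_sleep"):
        values.update(sleep_features(day.stream("fitbit_sleep")))
    values.update(phone_usage_features(day))
    if day.has("comm"):
        values.update(communication_features(day.stream("comm")))

    return FeatureVector(patient_id=day.patient_id, date=day.date, values=values)


def features_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Wide numeric frame (rows = patient-days); categoricals integer-encoded."""
    rows = []
    for v in vectors:
        row: dict[str, object] = {"patient_id": v.patient_id, "date": v.date}
        for name in FEATURE_NAMES:
            val = v.values.get(name, NA)
            if name in CATEGORICAL_FEATURES:
                row[name] = (encode_categorical(name, val)
                             if isinstance(val, str) else NA)
            else:
                row[name] = NA if val is None else float(val)
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "date", *FEATURE_NAMES])
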