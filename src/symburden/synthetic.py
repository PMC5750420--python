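"""Synthetic chemotherapy-cohort generator.

No raw patient data from mHealth symptom-monitoring studies of this kind
is publicly deposited, so the pipeline is exercised on a synthetic cohort
whose statistical structure mirrors the study design: ~2 chemotherapy
cycles (default 21 days) of phone sensor streams, Fitbit records and
twice-daily 12-symptom severity ratings per patient.

A latent daily symptom burden drives everything. Per patient it is a
patient-specific mean (Normal, centered near the burden scale's empirical
midpoint of ~16/120) plus a stationary AR(1) daily deviation — the
labeling scheme centers per patient, so between-patient mean differences
are present but must be irrelevant to the classes. The ``coupling``
parameter links the latent burden to behavior with the signs observed in
this literature: on high-symptom days patients take fewer steps in more
fragmented (more numerous, shorter) active bouts, move the phone less and
less variably, spend longer interacting with the screen in fewer
sessions, sleep longer with more awakenings, and stay home more.
``coupling = 0`` makes every stream statistically independent of burden.

Same config and seed ⇒ byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from datetime import date as Date
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConfigError, SYMPTOMS
from .ingest import write_stream

SENSOR_STREAMS = ("accel", "gps", "activity", "screen", "apps", "battery",
                  "comm", "fitbit_minutes", "fitbit_daily", "fitbit_sleep")

#: Features designed to be coupled to latent burden, with the expected
#: correlation sign (used by the sign-recovery checks).
COUPLED_FEATURE_SIGNS: dict[str, int] = {
    "steps": -1,
    "max_steps_per_min": -1,
    "n_sedentary_bouts": +1,
    "accel_mean": -1,
    "accel_sd": -1,
    "interaction_duration": +1,
    "unlocks_per_min": -1,
    "apps_per_min": -1,
    "min_fair": -1,
    "min_very": -1,
    "min_asleep": +1,
    "n_awakenings": +1,
}

# fixed per-symptom share of the composite (sums to 1; fatigue-heavy,
# dyspnea/numbness light, as in chemotherapy symptom inventories)
_SYMPTOM_WEIGHTS = np.array(
    [0.10, 0.12, 0.07, 0.08, 0.09, 0.09, 0.08, 0.08, 0.06, 0.06, 0.08, 0.09])
assert abs(_SYMPTOM_WEIGHTS.sum() - 1.0) < 1e-12 and len(_SYMPTOM_WEIGHTS) == 12


@dataclass
class CohortConfig:
    """Study-design knobs for the synthetic cohort."""

    n_patients: int = 10
    days_per_patient: int | tuple[int, ...] = 21
    symptom_scale_max: int = 10
    n_symptoms: int = 12
    coupling: float = 0.0
    missing_stream_prob: float = 0.1
    rng_seed: int = 0
    timezone: str = "America/New_York"
    start_date: Date = Date(2016, 2, 15)

    # latent-burden process
    patient_mean: float = 16.0
    patient_mean_sd: float = 4.0
    dev_sd: float = 8.0          # stationary sd of the AR(1) deviation
    ar_phi: float = 0.6

    # prompt behaviour
    skip_prob: float = 0.1
    rating_noise_sd: float = 1.0

    # behavioural noise multiplier and emission cadences
    behavior_noise: float = 1.0
    accel_period_s: float = 1.0
    gps_period_s: float = 180.0
    activity_period_s: float = 60.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        days = self.days_per_patient
        if isinstance(days, int):
            if days < 2:
                raise ConfigError("days_per_patient must be >= 2")
        else:
            if len(days) != self.n_patients or any(d < 2 for d in days):
                raise ConfigError(
                    "days_per_patient sequence must have one entry >= 2 "
                    "per patient")
        if self.n_symptoms != 12:
            raise ConfigError("n_symptoms must be 12")
        if self.symptom_scale_max != 10:
            raise ConfigError("symptom_scale_max must be 10")
        if self.coupling < 0:
            raise ConfigError("coupling must be >= 0")
        for f in ("missing_stream_prob", "skip_prob"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must be in [0, 1]")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ConfigError("ar_phi must be in [0, 1)")
        for f in ("dev_sd", "patient_mean_sd", "rating_noise_sd",
                  "behavior_noise"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        for f in ("accel_period_s", "gps_period_s", "activity_period_s"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f} must be > 0")

    def n_days(self, patient_index: int) -> int:
        if isinstance(self.days_per_patient, int):
            return self.days_per_patient
        return int(self.days_per_patient[patient_index])


def null_preset(n_patients: int = 10, days: int = 30,
                seed: int = 0) -> CohortConfig:
    """Null coupling at experiment cadence (accelerometer 1/60 Hz)."""
    return CohortConfig(n_patients=n_patients, days_per_patient=days,
                        coupling=0.0, rng_seed=seed,
                        accel_period_s=60.0, activity_period_s=120.0)


def low_preset(n_patients: int = 10, days: int = 30,
               seed: int = 0) -> CohortConfig:
    """Weak symptom→behavior coupling."""
    cfg = null_preset(n_patients, days, seed)
    cfg.coupling = 0.7
    return cfg


def strong_preset(n_patients: int = 10, days: int = 30,
                  seed: int = 0) -> CohortConfig:
    """Strong coupling: designed day-level feature-burden |r| >= 0.4.

    Behavioural noise is reduced and between-patient mean differences
    kept modest so that the within-patient fluctuations the labels encode
    dominate the feature variation.
    """
    cfg = null_preset(n_patients, days, seed)
    cfg.coupling = 2.0
    cfg.behavior_noise = 0.4
    cfg.patient_mean_sd = 3.0
    cfg.skip_prob = 0.05
    return cfg


@dataclass
class PatientData:
    patient_id: str
    start_date: Date
    end_date: Date
    streams: dict[str, pd.DataFrame]
    latent: pd.DataFrame  # date, latent_burden


@dataclass
class Cohort:
    config: CohortConfig
    patients: dict[str, PatientData]
    symptoms: pd.DataFrame
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# latent process


def _latent_series(cfg: CohortConfig, rng: np.random.Generator,
                   n_days: int) -> np.ndarray:
    mean = cfg.patient_mean + cfg.patient_mean_sd * rng.standard_normal()
    mean = float(np.clip(mean, 4.0, 60.0))
    dev = np.empty(n_days)
    dev[0] = cfg.dev_sd * rng.standard_normal()
    innov_sd = cfg.dev_sd * np.sqrt(1.0 - cfg.ar_phi ** 2)
    for t in range(1, n_days):
        dev[t] = cfg.ar_phi * dev[t - 1] + innov_sd * rng.standard_normal()
    return np.clip(mean + dev, 0.0, 110.0)


def _z(latent: float) -> float:
    """Standardised behavioural drive for one day."""
    return float(np.clip((latent - 16.0) / 10.0, -3.0, 3.0))


# ---------------------------------------------------------------------------
# symptom ratings


def generate_symptom_ratings(latent_burden: float, cfg: CohortConfig,
                             rng: np.random.Generator,
                             noise_sd: float | None = None
                             ) -> dict[str, np.ndarray]:
    """Morning and evening 12-symptom rating vectors for one day.

    Either prompt may be skipped with probability ``skip_prob`` (missed
    prompts); each returned vector holds integers in [0, 10]. With zero
    noise and latent burden at the scale floor every severity is 0.
    """
    if not np.isfinite(latent_burden):
        raise ValueError("latent_burden must be finite")
    sd = cfg.rating_noise_sd if noise_sd is None else noise_sd
    out: dict[str, np.ndarray] = {}
    for prompt in ("morning", "evening"):
        skip = rng.random() < cfg.skip_prob
        noise = sd * rng.standard_normal(12)
        if skip:
            continue
        sev = np.clip(np.rint(latent_burden * _SYMPTOM_WEIGHTS + noise),
                      0, cfg.symptom_scale_max).astype(int)
        out[prompt] = sev
    return out


# ---------------------------------------------------------------------------
# per-day stream emission


def _day_bounds(date: Date, tz: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    t0 = pd.Timestamp(datetime.combine(date, datetime.min.time()), tz=tz)
    t1 = pd.Timestamp(datetime.combine(date + timedelta(days=1),
                                       datetime.min.time()), tz=tz)
    return t0, t1


def _ts(t0: pd.Timestamp, seconds: np.ndarray) -> pd.Series:
    out = t0 + pd.to_timedelta(np.asarray(seconds, float), unit="s")
    return pd.Series(out).dt.round("ms")  # millisecond clock resolution


def _gen_fitbit_minutes(rng, cz, bn, t0, n_min):
    n_bouts = max(1, int(round(rng.normal(12.0 * np.exp(0.12 * cz), 2.0 * bn))))
    active = int(np.clip(round(140.0 * np.exp(-0.30 * cz)
                               * np.exp(rng.normal(0.0, 0.18 * bn))),
                         10, min(700, n_min - 2)))
    n_bouts = min(n_bouts, active)
    lengths = rng.multinomial(active - n_bouts, np.full(n_bouts, 1 / n_bouts)) + 1
    sed_total = n_min - active
    gaps = rng.multinomial(sed_total - (n_bouts + 1),
                           np.full(n_bouts + 1, 1 / (n_bouts + 1))) + 1
    steps = np.zeros(n_min, dtype=int)
    pos = 0
    base_intensity = 45.0 * np.exp(-0.35 * cz)
    for b in range(n_bouts):
        pos += gaps[b]
        inten = float(np.clip(np.exp(rng.normal(np.log(base_intensity), 0.5)),
                              2.0, 160.0))
        seg = np.clip(rng.poisson(inten, lengths[b]), 1, 200)
        steps[pos:pos + lengths[b]] = seg
        pos += lengths[b]
    minutes = pd.DataFrame({
        "timestamp": _ts(t0, np.arange(n_min) * 60.0),
        "steps": steps})
    total = int(steps.sum())
    per_min = steps
    daily = {
        "steps": total,
        "distance_m": round(0.75 * total, 1),
        "floors": int(rng.poisson(6.0 * np.exp(-0.25 * cz))),
        "min_light": int(((per_min >= 1) & (per_min <= 49)).sum()),
        "min_fair": int(((per_min >= 50) & (per_min <= 99)).sum()),
        "min_very": int((per_min >= 100).sum()),
    }
    return minutes, daily


def _gen_accel(rng, cz, bn, t0, day_s, period_s):
    n = max(2, int(day_s // period_s))
    mag = 9.81 + 0.05 * rng.standard_normal(n)
    p_move = float(np.clip(0.08 * np.exp(-0.30 * cz), 0.005, 0.5))
    amp = 2.0 * np.exp(-0.25 * cz)
    moving = rng.random(n) < p_move
    mag = mag + moving * np.abs(rng.normal(0.0, amp * max(bn, 0.2), n))
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    xyz = v * mag[:, None]
    return pd.DataFrame({
        "timestamp": _ts(t0, np.arange(n) * period_s),
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]})


def _gen_gps(rng, cz, t0, day_s, period_s, centers):
    n_blocks = 8
    block_s = day_s / n_blocks
    p_home = 1.0 / (1.0 + np.exp(-(0.8 + 0.5 * cz)))
    assign = []
    for b in range(n_blocks):
        if b < 2 or rng.random() < p_home:
            assign.append("home")
        else:
            assign.append("clinic" if rng.random() < 0.3 else "other")
    times, lats, lons = [], [], []
    jitter_deg = 30.0 / 111_320.0  # ~30 m
    for b, where in enumerate(assign):
        ts = np.arange(b * block_s, (b + 1) * block_s, period_s)
        lat0, lon0 = centers[where]
        times.append(ts)
        lats.append(lat0 + jitter_deg * rng.standard_normal(len(ts)))
        lons.append(lon0 + jitter_deg * rng.standard_normal(len(ts)))
    return pd.DataFrame({
        "timestamp": _ts(t0, np.concatenate(times)),
        "lat": np.concatenate(lats), "lon": np.concatenate(lons),
        "accuracy": np.full(sum(len(t) for t in times), 20.0)})


def _gen_activity(rng, cz, t0, day_s, period_s):
    n = max(1, int(day_s // period_s))
    p_foot = float(np.clip(0.06 * np.exp(-0.30 * cz), 0.003, 0.4))
    u = rng.random(n)
    labels = np.where(u < p_foot, "on_foot",
                      np.where(u < p_foot + 0.02, "in_vehicle",
                               np.where(u < p_foot + 0.05, "tilting", "still")))
    return pd.DataFrame({"timestamp": _ts(t0, np.arange(n) * period_s),
                         "label": labels})


def _gen_phone_usage(rng, cz, bn, t0, day_s, app_pool, app_w):
    n_min = int(day_s // 60)
    n_sessions = max(1, int(rng.poisson(28.0 * np.exp(-0.15 * cz))))
    n_sessions = min(n_sessions, n_min // 3)
    starts = np.sort(rng.choice(n_min - 2, size=n_sessions, replace=False))
    mean_len = 2.2 * np.exp(0.50 * cz)
    screen_rows, app_rows = [], []
    for i, s in enumerate(starts):
        length = float(np.clip(np.exp(rng.normal(np.log(mean_len),
                                                 0.6 * max(bn, 0.2))),
                               0.2, 120.0))
        limit = (starts[i + 1] - s - 0.05) if i + 1 < n_sessions else (n_min - s - 0.05)
        length = min(length, float(limit))
        s_t, e_t = s * 60.0, (s + length) * 60.0
        screen_rows.append((s_t, "unlock"))
        screen_rows.append((e_t, "lock"))
        n_apps = 1 + int(rng.poisson(0.8))
        shares = rng.dirichlet(np.ones(n_apps))
        pos = s_t
        for share in shares:
            app = str(rng.choice(app_pool, p=app_w))
            app_rows.append((pos, app, "foreground_start"))
            pos += share * (e_t - s_t)
            app_rows.append((min(pos, e_t), app, "foreground_end"))
    screen = pd.DataFrame(screen_rows, columns=["sec", "state"])
    screen = pd.DataFrame({"timestamp": _ts(t0, screen["sec"].to_numpy()),
                           "state": screen["state"]})
    apps = pd.DataFrame(app_rows, columns=["sec", "app_id", "event"])
    apps = pd.DataFrame({"timestamp": _ts(t0, apps["sec"].to_numpy()),
                         "app_id": apps["app_id"], "event": apps["event"]})
    return screen, apps


def _gen_battery(rng, bn, t0, day_s):
    rows = []
    n = 1 + int(rng.random() < 0.3)
    for _ in range(n):
        start = float(rng.normal(0.75 * day_s, 0.05 * day_s))
        dur = float(np.clip(rng.normal(150.0, 40.0 * max(bn, 0.2)), 30, 300)) * 60
        start = float(np.clip(start, 0, day_s - 120))
        end = min(start + dur, day_s - 1.0)
        rows.append((start, "charging_start"))
        rows.append((end, "charging_end"))
    rows.sort()
    return pd.DataFrame({"timestamp": _ts(t0, np.array([r[0] for r in rows])),
                         "state": [r[1] for r in rows]})


def _gen_comm(rng, cz, t0, day_s, hash_pool, hash_w):
    rows = []

    def emit(n, channel, direction, dur_scale):
        for _ in range(n):
            t = float(rng.uniform(6 * 3600, day_s - 60))
            h = str(rng.choice(hash_pool, p=hash_w))
            dur = float(np.rint(rng.exponential(dur_scale))) if dur_scale else 0.0
            rows.append((t, channel, direction, h, dur))

    emit(int(rng.poisson(1.2)), "call", "incoming", 180.0)
    emit(int(rng.poisson(1.2)), "call", "outgoing", 180.0)
    emit(int(rng.poisson(0.6 * np.exp(-0.25 * cz))), "call", "missed", 0.0)
    emit(int(rng.poisson(2.5)), "sms", "incoming", 0.0)
    emit(int(rng.poisson(2.5)), "sms", "outgoing", 0.0)
    rows.sort()
    return pd.DataFrame({
        "timestamp": _ts(t0, np.array([r[0] for r in rows])),
        "channel": [r[1] for r in rows],
        "direction": [r[2] for r in rows],
        "correspondent_hash": [r[3] for r in rows],
        "duration_s": [r[4] for r in rows]})


def _gen_sleep(rng, cz, bn, date):
    asleep = int(np.clip(round(420.0 * np.exp(0.10 * cz)
                               + rng.normal(0.0, 25.0 * max(bn, 0.2))),
                         180, 840))
    n_aw = int(rng.poisson(2.5 * np.exp(0.22 * cz)))
    awake = int(np.clip(round(n_aw * rng.normal(9.0, 2.0)), 0, 180))
    in_bed = asleep + awake + int(rng.integers(0, 20))
    return {"date": date, "min_asleep": asleep, "min_awake": awake,
            "n_awakenings": n_aw, "min_in_bed": in_bed}


# ---------------------------------------------------------------------------
# cohort assembly


def _patient_pools(rng):
    centers = {"home": (40.44 + rng.normal(0, 0.02), -79.95 + rng.normal(0, 0.02))}
    centers["clinic"] = (centers["home"][0] + 0.025, centers["home"][1] + 0.010)
    centers["other"] = (centers["home"][0] - 0.012, centers["home"][1] + 0.015)
    app_pool = [f"app{j:02d}" for j in range(8)]
    app_w = np.array([0.30, 0.20, 0.15, 0.10, 0.10, 0.06, 0.05, 0.04])
    # a pool of 10 hashed correspondents (patients hand their number to
    # their 10 most frequent contacts)
    hash_pool = ["%08x" % zlib.crc32(bytes(rng.integers(0, 256, 8).tolist()))
                 for _ in range(10)]
    hash_w = np.array([0.25, 0.18, 0.14, 0.11, 0.09, 0.07, 0.06, 0.05,
                       0.03, 0.02])
    return centers, app_pool, app_w / app_w.sum(), hash_pool, hash_w / hash_w.sum()


def generate_patient(cfg: CohortConfig, patient_index: int,
                     rng: np.random.Generator) -> tuple[PatientData, pd.DataFrame]:
    """All streams and symptom ratings for one patient."""
    pid = f"P{patient_index + 1:02d}"
    n_days = cfg.n_days(patient_index)
    start = cfg.start_date
    end = start + timedelta(days=n_days - 1)
    centers, app_pool, app_w, hash_pool, hash_w = _patient_pools(rng)
    latent = _latent_series(cfg, rng, n_days)

    drop = {s: (rng.random() < cfg.missing_stream_prob) for s in SENSOR_STREAMS}
    if all(drop.values()):
        drop["screen"] = False  # a patient with no sensors at all is useless

    acc, gps, act, scr, app, bat, com, fmin, fday, fsleep = ([] for _ in range(10))
    sym_rows = []
    bn = cfg.behavior_noise
    for d in range(n_days):
        date = start + timedelta(days=d)
        t0, t1 = _day_bounds(date, cfg.timezone)
        day_s = (t1 - t0).total_seconds()
        n_min = int(day_s // 60)
        cz = cfg.coupling * _z(latent[d])

        if not drop["accel"]:
            acc.append(_gen_accel(rng, cz, bn, t0, day_s, cfg.accel_period_s))
        if not drop["gps"]:
            gps.append(_gen_gps(rng, cz, t0, day_s, cfg.gps_period_s, centers))
        if not drop["activity"]:
            act.append(_gen_activity(rng, cz, t0, day_s, cfg.activity_period_s))
        if not (drop["screen"] and drop["apps"]):
            s_df, a_df = _gen_phone_usage(rng, cz, bn, t0, day_s, app_pool, app_w)
            if not drop["screen"]:
                scr.append(s_df)
            if not drop["apps"]:
                app.append(a_df)
        if not drop["battery"]:
            bat.append(_gen_battery(rng, bn, t0, day_s))
        if not drop["comm"]:
            com.append(_gen_comm(rng, cz, t0, day_s, hash_pool, hash_w))
        if not (drop["fitbit_minutes"] and drop["fitbit_daily"]):
            minutes, daily = _gen_fitbit_minutes(rng, cz, bn, t0, n_min)
            if not drop["fitbit_minutes"]:
                fmin.append(minutes)
            if not drop["fitbit_daily"]:
                fday.append({"date": date, **daily})
        if not drop["fitbit_sleep"]:
            fsleep.append(_gen_sleep(rng, cz, bn, date))

        prompts = generate_symptom_ratings(float(latent[d]), cfg, rng)
        prompt_secs = {"morning": 8 * 3600, "evening": 20 * 3600}
        for prompt, sev in prompts.items():
            t = t0 + pd.Timedelta(seconds=prompt_secs[prompt]
                                  + float(rng.normal(0, 900)))
            t = min(max(t, t0), t1 - pd.Timedelta(seconds=1))
            sym_rows.append({"patient_id": pid, "timestamp": t,
                             **{s: int(v) for s, v in zip(SYMPTOMS, sev)}})

    def cat(frames):
        return (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame())

    streams = {}
    stream_frames = {
        "accel": cat(acc), "gps": cat(gps), "activity": cat(act),
        "screen": cat(scr), "apps": cat(app), "battery": cat(bat),
        "comm": cat(com), "fitbit_minutes": cat(fmin),
        "fitbit_daily": pd.DataFrame(fday), "fitbit_sleep": pd.DataFrame(fsleep),
    }
    for name, df in stream_frames.items():
        if not drop[name]:
            streams[name] = df
    patient = PatientData(
        patient_id=pid, start_date=start, end_date=end, streams=streams,
        latent=pd.DataFrame({
            "date": [start + timedelta(days=i) for i in range(n_days)],
            "latent_burden": latent}))
    symptoms = pd.DataFrame(
        sym_rows, columns=["patient_id", "timestamp", *SYMPTOMS])
    return patient, symptoms


def generate_cohort(config: CohortConfig,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate the whole cohort; optionally write the raw files.

    Writes one directory per patient (``P01/accel.csv`` ...), a
    cohort-level ``symptoms.csv`` and a ``manifest.json`` naming patients,
    date ranges and present streams.
    """
    config.validate()
    root = np.random.SeedSequence(config.rng_seed)
    children = root.spawn(config.n_patients)
    patients: dict[str, PatientData] = {}
    sym_frames = []
    for i in range(config.n_patients):
        p, sym = generate_patient(config, i, np.random.default_rng(children[i]))
        patients[p.patient_id] = p
        sym_frames.append(sym)
    symptoms = (pd.concat(sym_frames, ignore_index=True) if sym_frames
                else pd.DataFrame(columns=["patient_id", "timestamp", *SYMPTOMS]))
    manifest = {
        "config": {k: (str(v) if isinstance(v, Date) else v)
                   for k, v in asdict(config).items()},
        "patients": {
            pid: {"start_date": str(p.start_date), "end_date": str(p.end_date),
                  "streams": sorted(p.streams)}
            for pid, p in patients.items()},
    }
    cohort = Cohort(config=config, patients=patients, symptoms=symptoms,
                    manifest=manifest)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, p in sorted(cohort.patients.items()):
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        for name, df in sorted(p.streams.items()):
            write_stream(df, pdir / f"{name}.csv", name)
    write_stream(cohort.symptoms, out / "symptoms.csv", "symptoms")
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .ingest import read_stream

    root = Path(in_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cfgd = dict(manifest["config"])
    cfgd["start_date"] = Date.fromisoformat(cfgd["start_date"])
    if isinstance(cfgd.get("days_per_patient"), list):
        cfgd["days_per_patient"] = tuple(cfgd["days_per_patient"])
    config = CohortConfig(**cfgd)
    tz = config.timezone
    patients = {}
    for pid, meta in sorted(manifest["patients"].items()):
        streams = {name: read_stream(root / pid / f"{name}.csv", name, tz=tz)
                   for name in meta["streams"]}
        patients[pid] = PatientData(
            patient_id=pid,
            start_date=Date.fromisoformat(meta["start_date"]),
            end_date=Date.fromisoformat(meta["end_date"]),
            streams=streams, latent=pd.DataFrame())
    symptoms = read_stream(root / "symptoms.csv", "symptoms", tz=tz)
    return Cohort(config=config, patients=patients, symptoms=symptoms,
                  manifest=manifest)
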