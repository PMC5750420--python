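"""Day-level feature extraction against naive reference implementations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symburden.datatypes import SensorDay
from symburden.features import (
    DEFAULT_EPS_M, FEATURE_NAMES, accel_magnitude_features, activity_features,
    assemble_feature_vector, cluster_day_locations, communication_features,
    detect_bouts, fitbit_activity_features, feature_group, haversine_m,
    location_features, match_global_locations, phone_usage_features,
    sleep_features, LocationCluster)
from symburden.datatypes import RegistryError

import reference_impl as ref

from conftest import DAY


# ---------------------------------------------------------------------------
# accelerometer


class TestAccelMagnitude:
    def test_matches_reference_on_fixture(self, fixture_day):
        got = accel_magnitude_features(fixture_day.stream("accel"))
        samples = list(zip(fixture_day.stream("accel")["x"],
                           fixture_day.stream("accel")["y"],
                           fixture_day.stream("accel")["z"]))
        want = ref.ref_accel_stats(samples)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-9)

    def test_hand_values(self):
        # magnitudes 1,2,3,4: sample sd = sqrt(5/3)
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                           "y": [0.0] * 4, "z": [0.0] * 4})
        got = accel_magnitude_features(df)
        assert got["accel_min"] == 1 and got["accel_max"] == 4
        assert got["accel_mean"] == 2.5 and got["accel_median"] == 2.5
        assert got["accel_sd"] == pytest.approx(math.sqrt(5 / 3), abs=1e-4)

    def test_constant_and_degenerate(self):
        const = pd.DataFrame({"x": [0.0] * 3, "y": [0.0] * 3, "z": [9.81] * 3})
        got = accel_magnitude_features(const)
        assert got["accel_min"] == got["accel_max"] == got["accel_mean"] == 9.81
        assert got["accel_sd"] == 0.0
        single = accel_magnitude_features(const.iloc[:1])
        assert np.isnan(single["accel_sd"])
        assert single["accel_mean"] == 9.81
        empty = accel_magnitude_features(const.iloc[:0])
        assert all(np.isnan(v) for v in empty.values())

    @given(st.lists(st.floats(0.1, 50), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_reorder_invariance(self, mags):
        df = pd.DataFrame({"x": mags, "y": [0.0] * len(mags),
                           "z": [0.0] * len(mags)})
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a, b = accel_magnitude_features(df), accel_magnitude_features(shuffled)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)


# ---------------------------------------------------------------------------
# activity recognition


@pytest.mark.parametrize("labels,want", [
    (["still", "still", "on_foot", "still"],
     {"n_activities": 2, "most_common_activity": "still",
      "n_activity_changes": 2}),
    (["still"] * 5,
     {"n_activities": 1, "most_common_activity": "still",
      "n_activity_changes": 0}),
    # tie between on_foot and on_bicycle -> lexicographically smaller
    (["on_foot", "on_bicycle"],
     {"n_activities": 2, "most_common_activity": "on_bicycle",
      "n_activity_changes": 1}),
])
def test_activity_features(labels, want):
    got = activity_features(pd.DataFrame({"label": labels}))
    for k, v in want.items():
        assert got[k] == v
    assert got == {**got, **ref.ref_activity(labels)}


def test_activity_empty_is_missing():
    got = activity_features(pd.DataFrame({"label": []}))
    assert all(v is np.nan or (isinstance(v, float) and np.isnan(v))
               for v in got.values())


# ---------------------------------------------------------------------------
# location


def _fixes(points, start="2016-02-15T09:00:00-05:00", spacing_min=10):
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "timestamp": [t0 + pd.Timedelta(minutes=spacing_min * i)
                      for i in range(len(points))],
        "lat": [p[0] for p in points], "lon": [p[1] for p in points],
        "accuracy": 10.0})


class TestLocationClustering:
    def test_single_point_one_cluster(self):
        fixes = _fixes([(40.0, -80.0)] * 6)
        clusters, labels = cluster_day_locations(fixes)
        assert len(clusters) == 1
        assert clusters[0].n_fixes == 6
        assert set(labels) == {0}

    def test_two_planted_centers_recovered(self):
        rng = np.random.default_rng(1)
        jitter = 30.0 / 111_320.0
        pts = [(40.0 + jitter * rng.standard_normal(),
                -80.0 + jitter * rng.standard_normal()) for _ in range(10)]
        pts += [(40.045 + jitter * rng.standard_normal(),
                 -80.0 + jitter * rng.standard_normal()) for _ in range(10)]
        clusters, _ = cluster_day_locations(_fixes(pts), eps_m=100, min_samples=5)
        assert len(clusters) == 2
        d0 = min(float(haversine_m(c.centroid[0], c.centroid[1], 40.0, -80.0))
                 for c in clusters)
        d1 = min(float(haversine_m(c.centroid[0], c.centroid[1], 40.045, -80.0))
                 for c in clusters)
        assert d0 < 50 and d1 < 50

    def test_too_few_fixes_no_cluster(self):
        clusters, labels = cluster_day_locations(_fixes([(40.0, -80.0)] * 3))
        assert clusters == [] and set(labels) == {-1}

    def test_global_matching(self):
        day_clusters = {}
        for d in range(7):
            day_clusters[d] = [
                LocationCluster(0, (40.0, -80.0), 600.0, 50),
                LocationCluster(1, (40.045, -80.0), 200.0, 20)]
        globals_, mapping = match_global_locations(day_clusters)
        assert len(globals_) == 2
        counts = {}
        for (_, _), gid in mapping.items():
            counts[gid] = counts.get(gid, 0) + 1
        assert sorted(counts.values()) == [7, 7]
        # a far-away one-day outlier founds its own global
        day_clusters[7] = [LocationCluster(0, (41.0, -81.0), 100.0, 10)]
        globals_, _ = match_global_locations(day_clusters)
        assert len(globals_) == 3


class TestLocationFeatures:
    def test_single_cluster_entropy_rog_zero(self):
        c = [LocationCluster(0, (40.0, -80.0), 900.0, 10)]
        got = location_features(c, _fixes([(40.0, -80.0)] * 6), top_mode="day")
        assert got["location_entropy"] == 0.0
        assert got["radius_of_gyration"] == 0.0
        assert got["n_unique_locations"] == 1

    def test_equal_dwell_entropy_ln2(self):
        cs = [LocationCluster(0, (40.0, -80.0), 300.0, 5),
              LocationCluster(1, (40.045, -80.0), 300.0, 5)]
        got = location_features(cs, None, top_mode="day")
        assert got["location_entropy"] == pytest.approx(math.log(2), abs=1e-12)

    def test_equal_dwell_1000m_apart_rog_500(self):
        # centroids 1000 m apart on a meridian; equal dwell -> rog = 500 m
        dlat = 1000.0 / (6_371_000.0 * math.pi / 180.0)
        cs = [LocationCluster(0, (40.0, -80.0), 300.0, 5),
              LocationCluster(1, (40.0 + dlat, -80.0), 300.0, 5)]
        got = location_features(cs, None, top_mode="day")
        assert got["radius_of_gyration"] == pytest.approx(500.0, rel=1e-3)
        want = ref.ref_radius_of_gyration(
            [c.centroid for c in cs], [c.dwell_min for c in cs])
        assert got["radius_of_gyration"] == pytest.approx(want, rel=1e-9)

    def test_travel_distance_matches_reference(self, fixture_day):
        fixes = fixture_day.stream("gps")
        got = location_features([], fixes)
        coords = list(zip(fixes["lat"], fixes["lon"]))
        assert got["travel_distance"] == pytest.approx(
            ref.ref_travel_distance(coords), rel=1e-9)
        assert np.isnan(got["location_entropy"])  # no clusters given

    def test_entropy_bounded_by_log_n(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(1, 6))
            cs = [LocationCluster(i, (40.0 + 0.1 * i, -80.0),
                                  float(rng.uniform(1, 500)), 5)
                  for i in range(n)]
            got = location_features(cs, None, top_mode="day")
            assert -1e-12 <= got["location_entropy"] <= math.log(n) + 1e-12


# ---------------------------------------------------------------------------
# Fitbit bouts


class TestBouts:
    def test_spec_example(self):
        steps = [0, 0, 7, 0, 0, 0, 12, 5, 0]
        df = pd.DataFrame({
            "timestamp": pd.date_range("2016-02-15 08:00", periods=9,
                                       freq="min", tz="America/New_York"),
            "steps": steps})
        got = fitbit_activity_features(None, df)
        assert got["n_sedentary_bouts"] == 3
        assert got["sedentary_bout_min_len"] == 1
        assert got["sedentary_bout_max_len"] == 3
        assert got["sedentary_bout_mean_len"] == 2.0
        assert got["n_active_bouts"] == 2
        assert got["active_bout_mean_len"] == 1.5
        assert got["active_bout_max_steps"] == 17
        assert got["active_bout_mean_steps"] == 12
        assert got["max_steps_per_min"] == 12
        want = ref.ref_fitbit_minutes(steps)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-9), k

    @pytest.mark.parametrize("steps,n_sed,n_act", [
        ([0] * 10, 1, 0),
        ([3] * 10, 0, 1),
        ([0, 1, 0, 1, 0, 1], 3, 3),
        ([4], 0, 1),
    ])
    def test_degenerate_patterns(self, steps, n_sed, n_act):
        df = pd.DataFrame({
            "timestamp": pd.date_range("2016-02-15", periods=len(steps),
                                       freq="min", tz="America/New_York"),
            "steps": steps})
        bouts = detect_bouts(df)
        assert sum(b.kind == "sedentary" for b in bouts) == n_sed
        assert sum(b.kind == "active" for b in bouts) == n_act

    def test_coverage_gap_splits_bout(self):
        t = pd.to_datetime(["2016-02-15 08:00", "2016-02-15 08:01",
                            "2016-02-15 08:10", "2016-02-15 08:11"]
                           ).tz_localize("America/New_York")
        df = pd.DataFrame({"timestamp": t, "steps": [0, 0, 0, 0]})
        bouts = detect_bouts(df)
        assert len(bouts) == 2
        assert all(b.kind == "sedentary" and b.length == 2 for b in bouts)

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_alternation(self, steps):
        df = pd.DataFrame({
            "timestamp": pd.date_range("2016-02-15", periods=len(steps),
                                       freq="min", tz="America/New_York"),
            "steps": steps})
        bouts = detect_bouts(df)
        assert sum(b.length for b in bouts) == len(steps)
        kinds = [b.kind for b in bouts]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        n_sed = kinds.count("sedentary")
        n_act = kinds.count("active")
        assert abs(n_sed - n_act) <= 1
        assert all((b.total_steps == 0) == (b.kind == "sedentary")
                   for b in bouts)
        want = ref.ref_bouts(list(steps))
        assert [(b.kind, b.length, b.total_steps) for b in bouts] == want


# ---------------------------------------------------------------------------
# sleep / phone usage / communication


def test_sleep_passthrough_and_missing(fixture_day):
    got = sleep_features(fixture_day.stream("fitbit_sleep"))
    assert got == {"min_asleep": 420, "min_awake": 30, "n_awakenings": 3,
                   "min_in_bed": 455}
    empty = sleep_features(None)
    assert all(np.isnan(v) for v in empty.values())


def test_sleep_integrity_warning_keeps_record():
    bad = pd.DataFrame({"date": [DAY], "min_asleep": [420], "min_awake": [60],
                        "n_awakenings": [2], "min_in_bed": [455]})
    with pytest.warns(UserWarning, match="time in bed"):
        got = sleep_features(bad)
    assert got["min_asleep"] == 420


def test_phone_usage_fixture_matches_reference(fixture_day):
    got = phone_usage_features(fixture_day)
    want_screen = ref.ref_screen(
        [(600, "unlock"), (630, "lock"), (720, "unlock"), (730, "off")], 1440)
    assert got["interaction_duration"] == pytest.approx(
        want_screen["interaction_duration"], abs=1e-9)  # 40 min
    assert got["unlocks_per_min"] == pytest.approx(
        want_screen["unlocks_per_min"], abs=1e-12)
    want_apps = ref.ref_apps(
        [("appA", 600, 605), ("appB", 605, 608), ("appA", 608, 610)], 1440)
    assert got["app_use_time"] == pytest.approx(10.0, abs=1e-9)
    assert got["n_unique_apps"] == want_apps["n_unique_apps"] == 2
    assert got["n_app_changes"] == want_apps["n_app_changes"] == 2
    assert got["apps_per_min"] == pytest.approx(want_apps["apps_per_min"])
    assert got["charge_duration"] == pytest.approx(60.0, abs=1e-9)


def test_phone_usage_no_unlocks_is_zero():
    day = SensorDay("P", DAY, streams={"screen": pd.DataFrame(
        {"timestamp": [], "state": []})},
        intervals={"screen_sessions": pd.DataFrame()},
        present={"screen": True})
    got = phone_usage_features(day)
    assert got["interaction_duration"] == 0.0
    assert got["unlocks_per_min"] == 0.0
    assert np.isnan(got["app_use_time"])  # apps stream absent


def test_communication_fixture(fixture_day):
    got = communication_features(fixture_day.stream("comm"))
    want = ref.ref_comm([("call", "incoming", "h1", 60.0),
                         ("call", "incoming", "h1", 30.0),
                         ("call", "missed", "h2", 0.0),
                         ("sms", "outgoing", "h3", 0.0)])
    for k, v in want.items():
        assert got[k] == v, k
    assert got["n_in_calls"] == 2 and got["dur_in_calls"] == 90.0
    assert got["n_missed_calls"] == 1 and got["n_unique_correspondents"] == 3
    assert got["most_frequent_contact"] == "h1"


def test_communication_empty_vs_absent():
    empty = communication_features(pd.DataFrame(
        columns=["channel", "direction", "correspondent_hash", "duration_s"]))
    assert empty["n_in_calls"] == 0.0
    assert np.isnan(empty["most_frequent_contact"])
    absent = communication_features(None)
    assert np.isnan(absent["n_in_calls"])


# ---------------------------------------------------------------------------
# assembly


def test_assemble_full_day_has_no_unexpected_missing(fixture_day):
    fv = assemble_feature_vector(fixture_day)
    missing = [n for n in FEATURE_NAMES if fv.is_missing(n)]
    assert missing == []

    # drop the Fitbit streams: those features go missing, phone intact
    day2 = SensorDay(fixture_day.patient_id, fixture_day.date,
                     streams={k: v for k, v in fixture_day.streams.items()
                              if not k.startswith("fitbit")},
                     intervals=fixture_day.intervals,
                     present={k: v for k, v in fixture_day.present.items()
                              if not k.startswith("fitbit")})
    fv2 = assemble_feature_vector(day2)
    assert fv2.is_missing("steps") and fv2.is_missing("min_asleep")
    assert not fv2.is_missing("accel_mean")
    assert not fv2.is_missing("interaction_duration")


def test_feature_group_registry():
    with pytest.raises(RegistryError):
        feature_group("bogus")
    fitbit = set(feature_group("fitbit"))
    phone = set(feature_group("phone"))
    assert fitbit.isdisjoint(phone)
    assert fitbit | phone == set(feature_group("all"))
    assert "steps" in fitbit and "accel_mean" in phone
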