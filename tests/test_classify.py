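"""Rotation forest, balancing resampler and the CV harnesses."""

import numpy as np
import pandas as pd
import pytest

from symburden.classify import (ClassifierConfig, ablation_by_source,
                                leave_one_day_out_cv, resample_balanced,
                                stratified_cv, train_rotation_forest)
from symburden.datatypes import LabeledDataset, RegistryError
from sklearn.ensemble import RandomForestClassifier


def _dataset(X, y, pid="P01"):
    n = len(y)
    pids = [pid] * n if isinstance(pid, str) else pid
    keys = pd.DataFrame({
        "patient_id": pids,
        "date": pd.date_range("2016-01-01", periods=n).date})
    names = [f"f{j}" for j in range(X.shape[1])]
    return LabeledDataset(X=pd.DataFrame(X, columns=names),
                          y=np.asarray(y, int), keys=keys)


def _gaussian_blobs(n=200, d=2, sep=6.0, seed=0, classes=(-1, 1)):
    rng = np.random.default_rng(seed)
    y = rng.choice(classes, n)
    X = rng.normal(size=(n, d)) + np.outer(y, np.full(d, sep / 2))
    return _dataset(X, y)


class TestResampleBalanced:
    def test_balancing_arithmetic(self):
        y = np.array([-1] * 10 + [0] * 1 + [1] * 5)
        ds = _dataset(np.zeros((16, 2)), y)
        out = resample_balanced(ds, seed=0)
        counts = {c: int(np.sum(out.y == c)) for c in (-1, 0, 1)}
        assert len(out) == 16
        assert counts[-1] == 6 and counts[0] == 5 and counts[1] == 5

    def test_uniform_preserved(self):
        y = np.repeat([-1, 0, 1], 4)
        out = resample_balanced(_dataset(np.zeros((12, 2)), y), seed=1)
        assert all(int(np.sum(out.y == c)) == 4 for c in (-1, 0, 1))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        ds = _dataset(rng.normal(size=(30, 3)), rng.choice([-1, 1], 30))
        a = resample_balanced(ds, seed=9)
        b = resample_balanced(ds, seed=9)
        pd.testing.assert_frame_equal(a.X, b.X)
        assert (a.y == b.y).all()

    def test_absent_class_is_error(self):
        ds = _dataset(np.zeros((10, 2)), np.repeat([-1, 1], 5))
        with pytest.raises(ValueError, match="0"):
            resample_balanced(ds, seed=0, classes=(-1, 0, 1))


class TestRotationForest:
    def test_separable_training_accuracy(self):
        ds = _gaussian_blobs(n=200, d=2, sep=6.0)
        model = train_rotation_forest(ds, ClassifierConfig(n_iterations=3,
                                                           n_trees=30), seed=0)
        pred = model.predict(ds.X)
        assert np.mean(pred == ds.y) >= 0.99

    def test_rotations_orthonormal(self):
        ds = _gaussian_blobs(n=100, d=7, sep=3.0, seed=2)
        model = train_rotation_forest(ds, ClassifierConfig(n_iterations=2,
                                                           n_trees=10), seed=1)
        for m in model.members:
            np.testing.assert_allclose(m.rotation @ m.rotation.T,
                                       np.eye(7), atol=1e-9)

    def test_identity_rotation_equals_plain_random_forest(self):
        ds = _gaussian_blobs(n=150, d=4, sep=2.0, seed=3)
        cfg = ClassifierConfig(n_iterations=1, subset_size=4, n_trees=50,
                               rotation="identity")
        model = train_rotation_forest(ds, cfg, seed=7)
        # rebuild the base forest with the same derived seed
        rng = np.random.default_rng(7)
        rng.permutation(4)
        rf = RandomForestClassifier(n_estimators=50,
                                    random_state=int(rng.integers(2 ** 31)),
                                    n_jobs=1)
        rf.fit(ds.X.to_numpy(float), ds.y)
        np.testing.assert_array_equal(model.predict(ds.X),
                                      rf.predict(ds.X.to_numpy(float)))

    def test_all_missing_row_predicts_via_medians(self):
        ds = _gaussian_blobs(n=100, d=3, sep=5.0, seed=4)
        model = train_rotation_forest(ds, ClassifierConfig(n_iterations=2,
                                                           n_trees=20), seed=0)
        row = pd.DataFrame([[np.nan] * 3], columns=ds.X.columns)
        pred = model.predict(row)
        assert pred[0] in (-1, 1)

    def test_unknown_feature_name_is_registry_error(self):
        ds = _gaussian_blobs(n=60, d=2, sep=5.0)
        model = train_rotation_forest(ds, ClassifierConfig(n_iterations=1,
                                                           n_trees=5), seed=0)
        bad = pd.DataFrame(np.zeros((1, 2)), columns=["f0", "zzz"])
        with pytest.raises(RegistryError):
            model.predict(bad)

    def test_empty_ensemble_error(self):
        ds = _gaussian_blobs(n=60, d=2, sep=5.0)
        model = train_rotation_forest(ds, ClassifierConfig(n_iterations=1,
                                                           n_trees=5), seed=0)
        model.members = []
        with pytest.raises(ValueError):
            model.predict(ds.X)


class TestStratifiedCV:
    def test_perfect_feature_gives_100(self):
        rng = np.random.default_rng(0)
        y = rng.choice([-1, 1], 120)
        X = np.column_stack([y.astype(float), rng.normal(size=120)])
        rep = stratified_cv(_dataset(X, y),
                            ClassifierConfig(n_iterations=2, n_trees=20,
                                             k_folds=5), seed=1)
        assert rep.accuracy == 100.0
        assert rep.confusion.sum() == 120

    def test_deterministic_report(self):
        rng = np.random.default_rng(1)
        y = rng.choice([-1, 1], 80)
        X = np.column_stack([y + rng.normal(0, 2, 80),
                             rng.normal(size=80)])
        cfg = ClassifierConfig(n_iterations=2, n_trees=10, k_folds=4)
        a = stratified_cv(_dataset(X, y), cfg, seed=3)
        b = stratified_cv(_dataset(X, y), cfg, seed=3)
        assert a.to_json() == b.to_json()

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        n = 300
        y = rng.permutation(np.repeat([-1, 0, 1], n // 3))
        X = rng.normal(size=(n, 5))
        rep = stratified_cv(_dataset(X, y),
                            ClassifierConfig(n_iterations=2, n_trees=20,
                                             k_folds=5), seed=4)
        # balanced 3-class chance = 33.3%; allow a generous CI
        assert 20.0 <= rep.accuracy <= 47.0

    def test_folds_partition_rows(self):
        rng = np.random.default_rng(3)
        y = rng.choice([-1, 1], 60)
        X = rng.normal(size=(60, 3))
        rep = stratified_cv(_dataset(X, y),
                            ClassifierConfig(n_iterations=1, n_trees=5,
                                             k_folds=6), seed=0)
        assert rep.confusion.sum() == 60
        assert len(rep.fold_accuracies) == 6

    def test_k_below_two_is_error(self):
        ds = _gaussian_blobs(n=30)
        with pytest.raises(ValueError):
            stratified_cv(ds, ClassifierConfig(k_folds=1), seed=0)

    def test_replication_mode_at_least_leakage_free(self):
        # resampling before folding leaks duplicated rows across the split
        rng = np.random.default_rng(5)
        y = rng.choice([-1, 1], 150)
        X = np.column_stack([y + rng.normal(0, 3.0, 150),
                             rng.normal(size=150)])
        base = ClassifierConfig(n_iterations=2, n_trees=20, k_folds=5)
        free = stratified_cv(_dataset(X, y), base, seed=6)
        repl = ClassifierConfig(**vars(base))
        repl.mode = "replication"
        leaky = stratified_cv(_dataset(X, y), repl, seed=6)
        assert leaky.accuracy >= free.accuracy


class TestLeaveOneDayOut:
    def test_deterministic_single_feature_patient(self):
        rng = np.random.default_rng(0)
        y = rng.choice([-1, 1], 12)
        X = np.column_stack([y.astype(float)])
        rep = leave_one_day_out_cv(_dataset(X, y),
                                   ClassifierConfig(n_iterations=2,
                                                    n_trees=20), seed=0)
        assert rep.accuracy == 100.0
        assert len(rep.fold_accuracies) == 12  # one fold per day

    def test_single_class_patient_skipped(self):
        ds = _dataset(np.zeros((8, 2)), np.ones(8))
        with pytest.raises(ValueError, match="single-class"):
            leave_one_day_out_cv(ds, ClassifierConfig(), seed=0)

    def test_too_few_days(self):
        ds = _dataset(np.zeros((4, 2)), np.array([-1, 1, -1, 1]))
        with pytest.raises(ValueError, match="fewer than 5"):
            leave_one_day_out_cv(ds, ClassifierConfig(), seed=0)


def test_ablation_groups_partition_and_identity():
    rng = np.random.default_rng(7)
    y = rng.choice([-1, 1], 90)
    X = np.column_stack([y + rng.normal(0, 1, 90), rng.normal(size=90),
                         rng.normal(size=90)])
    ds = _dataset(X, y)
    groups = {"a": ["f0", "f1"], "b": ["f2"], "empty": []}
    cfg = ClassifierConfig(n_iterations=1, n_trees=10, k_folds=3)
    with pytest.warns(UserWarning, match="empty"):
        reports = ablation_by_source(ds, groups, cfg, seed=1)
    assert set(reports) == {"a", "b"}
    seen = [f for g in ("a", "b") for f in groups[g]]
    assert sorted(seen) == ["f0", "f1", "f2"]  # disjoint cover
    # identity group equals plain stratified CV on the full set
    full = ablation_by_source(ds, {"all": ["f0", "f1", "f2"]}, cfg, seed=1)
    direct_cfg = ClassifierConfig(**vars(cfg))
    direct_cfg.selector = "none"
    direct = stratified_cv(ds, direct_cfg, seed=1)
    assert full["all"]["all"].to_json() == direct.to_json()
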