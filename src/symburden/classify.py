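"""Rotation-forest classification and the two evaluation schemes.

The rotation forest is an ensemble meta-learner: for each member, the
feature set is randomly partitioned into small disjoint subsets; within
each subset the principal axes of a bootstrapped class-subsample are
fitted and assembled into a block-diagonal orthonormal rotation; a base
learner (here a random forest) is then trained on the rotated data. All
principal components are retained — the transform is a pure rotation, no
truncation. Prediction is a majority vote over members (ties resolved by
greatest mean vote share, then lower class index).

Evaluation covers a population model (stratified k-fold CV over all
patients' days) and individual models (leave-one-day-out CV per patient).
Both run in a leakage-free mode — class-balancing resampling, feature
selection and imputation are fitted inside training folds only — and in a
replication mode where resampling/selection are applied to the full
dataset before folding. The replication mode matches the order of
operations many small mHealth studies describe; resampling with
replacement before folding places copies of a day on both sides of a
split, which inflates accuracy, so the leakage-free mode is the default
and the difference between the two is itself a reported quantity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .datatypes import CLASSES, LabeledDataset, RegistryError
from .features import feature_group
from .selection import cfs_search


@dataclass
class ClassifierConfig:
    """Rotation-forest and evaluation hyperparameters."""

    n_iterations: int = 10      # ensemble members
    subset_size: int = 3        # features per rotation block
    n_trees: int = 100          # trees per base random forest
    max_depth: int | None = None
    bootstrap_frac: float = 0.75  # row fraction for per-block PCA
    rotation: str = "pca"       # "pca" | "identity"
    k_folds: int = 10
    selector: str = "none"      # "none" | "cfs-pearson" | "cfs-su"
    resample: bool = True
    mode: str = "leakage_free"  # "leakage_free" | "replication"

    def light(self) -> "ClassifierConfig":
        """A cheaper profile for simulation sweeps (fewer members/trees)."""
        cfg = ClassifierConfig(**vars(self))
        cfg.n_iterations = 3
        cfg.n_trees = 30
        return cfg


@dataclass
class EvalReport:
    """Accuracy, confusion and per-fold detail for one evaluation run."""

    scheme: str
    accuracy: float                     # percent
    confusion: np.ndarray               # 3x3, rows = true class (-1,0,1)
    fold_accuracies: list[float]
    selected_features: list[list[str]]  # per fold (empty if no selection)
    seed: int
    n_days: int
    classes_present: list[int] = field(default_factory=list)

    def per_class_precision_recall(self) -> pd.DataFrame:
        c = self.confusion.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.diag(c) / c.sum(0)
            rec = np.diag(c) / c.sum(1)
        return pd.DataFrame({"class": list(CLASSES), "precision": prec,
                             "recall": rec})

    def to_json(self) -> str:
        d = {
            "scheme": self.scheme,
            "accuracy": round(self.accuracy, 6),
            "confusion": self.confusion.tolist(),
            "fold_accuracies": [round(a, 6) for a in self.fold_accuracies],
            "selected_features": self.selected_features,
            "seed": self.seed,
            "n_days": self.n_days,
            "classes_present": self.classes_present,
        }
        return json.dumps(d, sort_keys=True, indent=1)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(CLASSES)}
    c = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        c[idx[int(t)], idx[int(p)]] += 1
    return c


# ---------------------------------------------------------------------------
# class-balancing resampling


def resample_balanced(dataset: LabeledDataset, seed: int,
                      classes: tuple[int, ...] | None = None) -> LabeledDataset:
    """Resample with replacement to near-uniform class frequencies.

    The output has the same row count; per-class counts differ by at most
    one from floor(n / n_classes), the remainder seats going to the
    classes with the largest original counts (ties by class value).
    ``classes=None`` balances over the classes observed in the data;
    requesting a class that is absent is an error.
    """
    y = dataset.y
    if classes is None:
        classes = tuple(sorted(set(int(v) for v in y)))
    for c in classes:
        if not np.any(y == c):
            raise ValueError(f"class {c} absent from dataset; cannot balance")
    n = len(y)
    k = len(classes)
    base = n // k
    rem = n - base * k
    orig = {c: int(np.sum(y == c)) for c in classes}
    order = sorted(classes, key=lambda c: (-orig[c], c))
    target = {c: base for c in classes}
    for c in order[:rem]:
        target[c] += 1
    rng = np.random.default_rng(seed)
    picked = []
    for c in sorted(classes):
        pool = np.flatnonzero(y == c)
        picked.append(rng.choice(pool, size=target[c], replace=True))
    idx = np.concatenate(picked)
    return dataset.subset_rows(idx)


# ---------------------------------------------------------------------------
# rotation forest


@dataclass
class _Member:
    rotation: np.ndarray
    forest: RandomForestClassifier


@dataclass
class RotationForestModel:
    members: list[_Member]
    feature_names: list[str]
    medians: np.ndarray
    classes_: np.ndarray
    config: ClassifierConfig

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise RegistryError(
                    f"feature(s) {sorted(missing)} unknown to the model")
            X = X[self.feature_names]
        A = X.to_numpy(float).copy()
        for j in range(A.shape[1]):
            col = A[:, j]
            col[~np.isfinite(col)] = self.medians[j]
        return A

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not self.members:
            raise ValueError("empty ensemble")
        A = self._prepare(X)
        votes = np.zeros((len(A), len(self.classes_)))
        proba = np.zeros_like(votes)
        for m in self.members:
            Xr = A @ m.rotation
            pred = m.forest.predict(Xr)
            for i, c in enumerate(self.classes_):
                votes[:, i] += pred == c
            proba += m.forest.predict_proba(Xr)
        proba /= len(self.members)
        # majority vote; ties -> greatest mean vote share, then lower class
        out = np.empty(len(A), dtype=int)
        for i in range(len(A)):
            v = votes[i]
            cand = np.flatnonzero(v == v.max())
            if len(cand) > 1:
                p = proba[i, cand]
                cand = cand[p == p.max()]
            out[i] = self.classes_[cand[0]]
        return out


def _block_rotation(X: np.ndarray, subsets: list[np.ndarray], y: np.ndarray,
                    cfg: ClassifierConfig, rng: np.random.Generator) -> np.ndarray:
    d = X.shape[1]
    R = np.zeros((d, d))
    classes = np.unique(y)
    for cols in subsets:
        if cfg.rotation == "identity":
            R[np.ix_(cols, cols)] = np.eye(len(cols))
            continue
        # non-empty random class subset, then a bootstrap row subsample
        n_cls = rng.integers(1, len(classes) + 1)
        chosen = rng.choice(classes, size=n_cls, replace=False)
        rows = np.flatnonzero(np.isin(y, chosen))
        take = max(2, int(round(cfg.bootstrap_frac * len(rows))))
        rows = rng.choice(rows, size=take, replace=True)
        sub = X[np.ix_(rows, cols)]
        cov = np.cov(sub, rowvar=False)
        cov = np.atleast_2d(cov)
        # eigh of a PSD matrix always yields a full orthonormal basis,
        # even when the subsample is rank-deficient
        _, vecs = np.linalg.eigh(cov)
        R[np.ix_(cols, cols)] = vecs[:, ::-1]
    return R


def train_rotation_forest(dataset: LabeledDataset,
                          config: ClassifierConfig | None = None,
                          seed: int = 0) -> RotationForestModel:
    """Fit the rotation-forest ensemble (deterministic given the seed).

    Missing values are imputed with per-feature training medians (stored
    on the model); an all-missing feature imputes to 0.
    """
    cfg = config or ClassifierConfig()
    X = dataset.X
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data has a single class")
    if X.shape[1] < 1:
        raise ValueError("training data has no features")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(X.to_numpy(float), axis=0)
    medians = np.nan_to_num(medians)
    A = X.to_numpy(float).copy()
    for j in range(A.shape[1]):
        col = A[:, j]
        col[~np.isfinite(col)] = medians[j]

    d = A.shape[1]
    if d < cfg.subset_size:
        warnings.warn("fewer features than subset_size; using one subset")
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(cfg.n_iterations):
        perm = rng.permutation(d)
        subsets = [perm[i:i + cfg.subset_size]
                   for i in range(0, d, cfg.subset_size)]
        R = _block_rotation(A, subsets, y, cfg, rng)
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees, max_depth=cfg.max_depth,
            random_state=int(rng.integers(2 ** 31)), n_jobs=1)
        forest.fit(A @ R, y)
        members.append(_Member(rotation=R, forest=forest))
    return RotationForestModel(
        members=members, feature_names=list(X.columns), medians=medians,
        classes_=np.array(sorted(set(int(v) for v in y))), config=cfg)


# ---------------------------------------------------------------------------
# cross-validation schemes


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Per-class round-robin dealing into k folds.

    k is lowered (with a warning) only when even the largest class cannot
    fill k folds; classes rarer than the fold count simply appear in that
    many folds (lowering k to a near-empty class's count would destroy
    the cross-validation for everyone else).
    """
    counts = [int(np.sum(y == c)) for c in sorted(set(int(v) for v in y))]
    k_eff = max(2, min(k, max(counts)))
    if k_eff < k:
        warnings.warn(f"lowering k from {k} to {k_eff} (largest class size)")
    folds: list[list[int]] = [[] for _ in range(k_eff)]
    offset = 0
    for c in sorted(set(int(v) for v in y)):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for i, row in enumerate(idx):
            folds[(offset + i) % k_eff].append(int(row))
        offset += len(idx)
    return [np.array(sorted(f), dtype=int) for f in folds]


def _fit_fold(train: LabeledDataset, cfg: ClassifierConfig,
              seed: int) -> tuple[RotationForestModel, list[str]]:
    selected: list[str] = []
    if cfg.resample:
        train = resample_balanced(train, seed=seed)
    if cfg.selector.startswith("cfs"):
        mode = "su" if cfg.selector.endswith("su") else "pearson"
        selected = cfs_search(train, mode=mode).selected_features
        train = train.subset_features(selected)
    model = train_rotation_forest(train, cfg, seed=seed)
    return model, selected


def stratified_cv(dataset: LabeledDataset, config: ClassifierConfig | None = None,
                  seed: int = 0) -> EvalReport:
    """Population model: stratified k-fold CV pooled over all patients.

    In leakage-free mode resampling/selection/imputation happen inside
    each training fold; in replication mode they are applied to the full
    dataset before folding (and fold predictions reuse that global
    selection).
    """
    cfg = config or ClassifierConfig()
    if cfg.k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    data = dataset
    global_selected: list[str] = []
    if cfg.mode == "replication":
        if cfg.resample:
            data = resample_balanced(data, seed=seed)
        if cfg.selector.startswith("cfs"):
            mode = "su" if cfg.selector.endswith("su") else "pearson"
            global_selected = cfs_search(data, mode=mode).selected_features
            data = data.subset_features(global_selected)
    elif cfg.mode != "leakage_free":
        raise ValueError(f"unknown mode {cfg.mode!r}")

    folds = _stratified_folds(data.y, cfg.k_folds, rng)
    inner = ClassifierConfig(**vars(cfg))
    if cfg.mode == "replication":
        inner.resample = False
        inner.selector = "none"
    conf = np.zeros((3, 3), dtype=int)
    fold_acc, fold_sel = [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(data)), test_idx)
        train = data.subset_rows(train_idx)
        test = data.subset_rows(test_idx)
        model, selected = _fit_fold(train, inner, seed=int(rng.integers(2 ** 31)))
        Xt = test.X[selected] if selected else test.X
        pred = model.predict(Xt)
        conf += _confusion(test.y, pred)
        fold_acc.append(100.0 * float(np.mean(pred == test.y)))
        fold_sel.append(selected or global_selected)
    acc = 100.0 * np.trace(conf) / conf.sum()
    return EvalReport(
        scheme="stratified_cv", accuracy=float(acc), confusion=conf,
        fold_accuracies=fold_acc, selected_features=fold_sel, seed=seed,
        n_days=len(dataset),
        classes_present=sorted(set(int(v) for v in dataset.y)))


def leave_one_day_out_cv(dataset: LabeledDataset,
                         config: ClassifierConfig | None = None,
                         seed: int = 0) -> EvalReport:
    """Individual model: hold out each day of one patient in turn."""
    cfg = config or ClassifierConfig()
    pids = set(dataset.keys["patient_id"])
    if len(pids) != 1:
        raise ValueError("leave-one-day-out expects a single patient")
    if len(dataset) < 5:
        raise ValueError("patient has fewer than 5 labeled days")
    classes = sorted(set(int(v) for v in dataset.y))
    if len(classes) < 2:
        raise ValueError("single-class patient; skipped")
    rng = np.random.default_rng(seed)
    conf = np.zeros((3, 3), dtype=int)
    fold_acc, fold_sel = [], []
    for i in range(len(dataset)):
        train_idx = np.array([j for j in range(len(dataset)) if j != i])
        train = dataset.subset_rows(train_idx)
        test = dataset.subset_rows(np.array([i]))
        inner = ClassifierConfig(**vars(cfg))
        if len(set(int(v) for v in train.y)) < 2:
            # held-out day removed the only row of a class: predict the
            # training majority
            pred = np.array([int(pd.Series(train.y).mode().iloc[0])])
            selected = []
        else:
            model, selected = _fit_fold(train, inner,
                                        seed=int(rng.integers(2 ** 31)))
            Xt = test.X[selected] if selected else test.X
            pred = model.predict(Xt)
        conf += _confusion(test.y, pred)
        fold_acc.append(100.0 * float(pred[0] == test.y[0]))
        fold_sel.append(selected)
    acc = 100.0 * np.trace(conf) / conf.sum()
    return EvalReport(
        scheme="leave_one_day_out", accuracy=float(acc), confusion=conf,
        fold_accuracies=fold_acc, selected_features=fold_sel, seed=seed,
        n_days=len(dataset), classes_present=classes)


def ablation_by_source(dataset: LabeledDataset,
                       groups: dict[str, list[str]] | None = None,
                       config: ClassifierConfig | None = None,
                       seed: int = 0) -> dict[str, dict[str, EvalReport]]:
    """Stratified-CV report per device/category feature group.

    Each group is evaluated with all its features and again with CFS
    selection — the device-ablation experiment grid. ``groups`` defaults
    to the registry's named groups; empty groups are skipped with a
    warning.
    """
    cfg = config or ClassifierConfig()
    if groups is None:
        groups = {g: feature_group(g) for g in
                  ("fitbit", "phone", "movement", "activity", "location",
                   "phone_usage", "communication")}
    out: dict[str, dict[str, EvalReport]] = {}
    for name, feats in groups.items():
        feats = [f for f in feats if f in dataset.X.columns]
        if not feats:
            warnings.warn(f"group {name!r} is empty; skipped")
            continue
        sub = dataset.subset_features(feats)
        full_cfg = ClassifierConfig(**vars(cfg))
        full_cfg.selector = "none"
        sel_cfg = ClassifierConfig(**vars(cfg))
        sel_cfg.selector = "cfs-pearson"
        out[name] = {
            "all": stratified_cv(sub, full_cfg, seed=seed),
            "selected": stratified_cv(sub, sel_cfg, seed=seed),
        }
    return out
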