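"""Correlation-based feature subset selection (CFS).

CFS scores a candidate subset S of k features by the merit

    merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

where r̄_cf is the mean absolute feature–class correlation of the members
and r̄_ff the mean absolute pairwise feature–feature correlation: a good
subset is strongly related to the class and weakly related internally.
The search is best-first forward selection from the empty set, expanding
the best open subset by one feature at a time and stopping after a fixed
number of consecutive non-improving expansions.

Feature–class correlation treats the 3-class label {−1, 0, 1} as numeric
(ordered severity levels, equally spaced). An alternative mode discretizes
features and scores with symmetrical uncertainty, the information-theoretic
correlate used by classic CFS.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import pearson_pairwise
from .datatypes import LabeledDataset


@dataclass
class CfsResult:
    selected_features: list[str]
    merit: float
    mode: str
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


def cfs_merit(subset: list[str], r_cf: pd.Series, r_ff: pd.DataFrame) -> float:
    """Merit of a subset given |feature-class| and |feature-feature|
    correlation tables. Undefined correlations count as 0."""
    k = len(subset)
    if k == 0:
        raise ValueError("subset must be non-empty")
    rcf = np.nan_to_num(r_cf.loc[subset].to_numpy(float)).mean()
    if k == 1:
        return float(rcf)
    sub = np.nan_to_num(r_ff.loc[subset, subset].to_numpy(float))
    rff = (sub.sum() - np.trace(sub)) / (k * (k - 1))
    return float(k * rcf / np.sqrt(k + k * (k - 1) * rff))


# ---------------------------------------------------------------------------
# correlation tables


def _su_discretize(x: np.ndarray, bins: int = 3) -> np.ndarray:
    """Equal-frequency integer binning (NaN preserved as -1)."""
    out = np.full(len(x), -1)
    m = np.isfinite(x)
    if m.sum() == 0:
        return out
    ranks = pd.Series(x[m]).rank(method="average").to_numpy()
    out[m] = np.minimum((ranks - 1) * bins // m.sum(), bins - 1).astype(int)
    return out


def _symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    m = (a >= 0) & (b >= 0)
    if m.sum() < 3:
        return 0.0
    a, b = a[m], b[m]
    joint = pd.crosstab(a, b).to_numpy(float)
    p = joint / joint.sum()
    px, py = p.sum(1), p.sum(0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    hxy = -np.sum(p[p > 0] * np.log(p[p > 0]))
    if hx + hy == 0:
        return 0.0
    return float(2.0 * (hx + hy - hxy) / (hx + hy))


def correlation_tables(dataset: LabeledDataset,
                       mode: str = "pearson") -> tuple[pd.Series, pd.DataFrame]:
    """|feature-class| vector and |feature-feature| matrix, pairwise-complete.

    ``mode="pearson"`` uses absolute Pearson r with the numeric class;
    ``mode="su"`` uses symmetrical uncertainty on 3-bin discretized
    features. Undefined entries (zero variance, too few pairs) are 0.
    """
    names = dataset.feature_names
    X = dataset.X.to_numpy(float)
    y = dataset.y.astype(float)
    d = len(names)
    if mode == "pearson":
        rcf = np.zeros(d)
        for j in range(d):
            r, _ = pearson_pairwise(X[:, j], y)
            rcf[j] = abs(r) if np.isfinite(r) else 0.0
        rff = np.eye(d)
        for i in range(d):
            for j in range(i + 1, d):
                r, _ = pearson_pairwise(X[:, i], X[:, j])
                rff[i, j] = rff[j, i] = abs(r) if np.isfinite(r) else 0.0
    elif mode == "su":
        disc = np.stack([_su_discretize(X[:, j]) for j in range(d)], axis=1)
        ycls = y.astype(int) + 1
        rcf = np.array([_symmetrical_uncertainty(disc[:, j], ycls)
                        for j in range(d)])
        rff = np.eye(d)
        for i in range(d):
            for j in range(i + 1, d):
                rff[i, j] = rff[j, i] = _symmetrical_uncertainty(
                    disc[:, i], disc[:, j])
    else:
        raise ValueError(f"unknown CFS mode {mode!r}")
    return pd.Series(rcf, index=names), pd.DataFrame(rff, index=names, columns=names)


# ---------------------------------------------------------------------------
# best-first search


def cfs_search(dataset: LabeledDataset, max_stale: int = 5,
               mode: str = "pearson") -> CfsResult:
    """Best-first forward subset search maximising the CFS merit.

    Deterministic given input feature order: ties in merit break
    lexicographically on the subset's sorted names. When every
    feature-class correlation is zero the single alphabetically-first
    feature with the (tied) largest |r_cf| is returned with a warning.
    """
    names = dataset.feature_names
    if not names:
        raise ValueError("dataset has no features")
    r_cf, r_ff = correlation_tables(dataset, mode=mode)

    if float(r_cf.max()) == 0.0:
        warnings.warn("all feature-class correlations are zero; "
                      "returning a single arbitrary feature")
        pick = sorted(names)[0]
        return CfsResult([pick], 0.0, mode, [((pick,), 0.0)])

    trace: list[tuple[tuple[str, ...], float]] = []
    best_subset: tuple[str, ...] = ()
    best_merit = -np.inf
    # heap of (-merit, subset) open for expansion
    open_heap: list[tuple[float, tuple[str, ...]]] = [(0.0, ())]
    visited: set[tuple[str, ...]] = {()}
    stale = 0
    while open_heap and stale < max_stale:
        _, subset = heapq.heappop(open_heap)
        improved = False
        for f in names:
            if f in subset:
                continue
            child = tuple(sorted((*subset, f)))
            if child in visited:
                continue
            visited.add(child)
            m = cfs_merit(list(child), r_cf, r_ff)
            trace.append((child, m))
            heapq.heappush(open_heap, (-m, child))
            if m > best_merit + 1e-12:
                best_subset, best_merit = child, m
                improved = True
        stale = 0 if improved else stale + 1
    if not best_subset:  # only reachable if everything tied at -inf
        best_subset = (sorted(names)[0],)
        best_merit = cfs_merit(list(best_subset), r_cf, r_ff)
    return CfsResult(list(best_subset), float(best_merit), mode, trace)


def exhaustive_best_subset(dataset: LabeledDataset,
                           mode: str = "pearson") -> tuple[list[str], float]:
    """Exact maximiser of the merit over all non-empty subsets (small d only)."""
    from itertools import combinations

    names = dataset.feature_names
    if len(names) > 16:
        raise ValueError("exhaustive search is exponential; use <= 16 features")
    r_cf, r_ff = correlation_tables(dataset, mode=mode)
    best, best_m = None, -np.inf
    for k in range(1, len(names) + 1):
        for comb in combinations(sorted(names), k):
            m = cfs_merit(list(comb), r_cf, r_ff)
            if m > best_m + 1e-12:
                best, best_m = comb, m
    return list(best), float(best_m)
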