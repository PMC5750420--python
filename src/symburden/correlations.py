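"""Pairwise-complete Pearson screening of features against daily burden.

Each numeric feature is correlated with the continuous composite burden
score over the days where both are observed (pairwise, not listwise,
deletion — the usable N legitimately differs per feature because sensor
availability differs). The two-sided p-value comes from the exact t
reference distribution, t = r·sqrt((n−2)/(1−r²)) on n−2 df.

No multiple-testing correction is applied by default (the screening is
descriptive); a Benjamini–Hochberg column is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LabeledDataset
from .features import CATEGORICAL_FEATURES, FEATURE_REGISTRY


def pearson_pairwise(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson r over complete pairs; returns (r, n). r is NaN if n < 3
    or either side has zero variance."""
    m = np.isfinite(x) & np.isfinite(y)
    n = int(m.sum())
    if n < 3:
        return float("nan"), n
    xv, yv = x[m], y[m]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan"), n
    r = float(np.corrcoef(xv, yv)[0, 1])
    return max(-1.0, min(1.0, r)), n


def correlate_features(dataset: LabeledDataset,
                       bh_adjust: bool = False) -> pd.DataFrame:
    """One row per feature: category, feature, r, n, p (sorted by
    category then |r| descending). Zero-variance/undefined rows are
    excluded. Categorical features are not screened (Pearson r would be
    meaningless on arbitrary codes)."""
    if dataset.burden is None:
        raise ValueError("dataset carries no continuous burden scores")
    y = np.asarray(dataset.burden, dtype=float)
    rows = []
    for name in dataset.feature_names:
        if name in CATEGORICAL_FEATURES:
            continue
        r, n = pearson_pairwise(dataset.X[name].to_numpy(float), y)
        if not np.isfinite(r):
            continue
        if abs(r) >= 1.0:
            p = 0.0 if n > 2 else float("nan")
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        spec = FEATURE_REGISTRY.get(name)
        rows.append({"category": spec.category if spec else "",
                     "feature": name, "r": r, "n": n, "p": p})
    out = pd.DataFrame(rows, columns=["category", "feature", "r", "n", "p"])
    if len(out):
        out = out.sort_values(
            ["category", "r"], key=lambda s: s if s.name == "category"
            else -s.abs(), kind="stable").reset_index(drop=True)
        if bh_adjust:
            out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    return out
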