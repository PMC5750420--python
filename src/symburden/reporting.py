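"""Render pipeline outputs as publication-style tables and a run manifest.

The correlation table groups features by category and prints r without a
leading zero (".28", "−.28") the way psychology journals format it; the
machine-readable CSVs written elsewhere keep full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .classify import EvalReport

CATEGORY_ORDER = ("Mobility and activity", "Sleep", "Phone usage",
                  "Communication")


def format_r(r: float) -> str:
    """Leading-zero-free correlation formatting: −0.275 → '−.28'."""
    s = f"{abs(r):.2f}".lstrip("0")
    return ("−" if r < 0 else "") + s


def format_p(p: float) -> str:
    return "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0")


def render_table_correlations(corr: pd.DataFrame) -> pd.DataFrame:
    """Correlation screen in display form: category blocks, r to 2 decimals."""
    rows = []
    for cat in CATEGORY_ORDER:
        block = corr[corr["category"] == cat]
        for row in block.itertuples(index=False):
            rows.append({"category": cat, "feature": row.feature,
                         "r": format_r(row.r), "N": int(row.n),
                         "p": format_p(row.p)})
    return pd.DataFrame(rows, columns=["category", "feature", "r", "N", "p"])


GROUP_ORDER = ("fitbit", "phone", "movement", "activity", "location",
               "phone_usage", "communication")


def render_table_ablation(reports: dict[str, dict[str, EvalReport]]
                          ) -> pd.DataFrame:
    """Device/category ablation grid: per group, all vs selected features."""
    rows = []
    for group in GROUP_ORDER:
        if group not in reports:
            rows.append({"group": group, "features": "(absent)",
                         "accuracy_pct": ""})
            continue
        pair = reports[group]
        rows.append({"group": group, "features": "all",
                     "accuracy_pct": f"{pair['all'].accuracy:.1f}"})
        sel = pair["selected"].selected_features
        names = sorted(set(n for fold in sel for n in fold))
        rows.append({"group": group,
                     "features": "selected: " + ", ".join(names),
                     "accuracy_pct": f"{pair['selected'].accuracy:.1f}"})
    return pd.DataFrame(rows, columns=["group", "features", "accuracy_pct"])


def render_table_individual(per_patient: dict[str, dict[str, EvalReport]]
                            ) -> pd.DataFrame:
    """Per-patient leave-one-day-out summary plus an unweighted average row."""
    rows = []
    for pid in sorted(per_patient):
        pair = per_patient[pid]
        sel = pair["selected"].selected_features
        names = sorted(set(n for fold in sel for n in fold))
        rows.append({
            "patient": pid,
            "days": pair["all"].n_days,
            "accuracy_pct": round(pair["all"].accuracy, 1),
            "accuracy_selected_pct": round(pair["selected"].accuracy, 1),
            "selected_features": ", ".join(names)})
    cols = ["patient", "days", "accuracy_pct", "accuracy_selected_pct",
            "selected_features"]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        avg = {
            "patient": "Average",
            "days": round(float(out["days"].mean()), 1),
            "accuracy_pct": round(float(out["accuracy_pct"].mean()), 1),
            "accuracy_selected_pct": round(
                float(out["accuracy_selected_pct"].mean()), 1),
            "selected_features": "-"}
        out = pd.concat([out, pd.DataFrame([avg])], ignore_index=True)
    return out


def to_markdown(table: pd.DataFrame) -> str:
    header = "| " + " | ".join(table.columns) + " |"
    sep = "|" + "|".join("---" for _ in table.columns) + "|"
    lines = [header, sep]
    for row in table.itertuples(index=False):
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def run_manifest(config: dict, seeds: dict[str, int],
                 inputs: dict[str, str | Path] | None = None,
                 row_counts: dict[str, int] | None = None) -> dict:
    """Reproducibility manifest: config snapshot, seeds, input digests."""
    digests = {}
    for name, path in (inputs or {}).items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        digests[name] = h.hexdigest()
    from . import __version__
    return {"config": config, "seeds": seeds, "input_digests": digests,
            "row_counts": row_counts or {}, "version": __version__}


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
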