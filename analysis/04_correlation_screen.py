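"""Correlation screen: each feature against the continuous burden score.

Pairwise-complete Pearson r with exact t-based p-values; N varies per
feature with sensor availability. Writes the machine-readable
``results/correlations.csv`` and a journal-style rendering.
"""

from _common import RESULTS, ensure_dirs, strong_cohort
from symburden.correlations import correlate_features
from symburden.pipeline import cohort_dataset
from symburden.reporting import render_table_correlations, to_markdown

ensure_dirs()
ds, _, _ = cohort_dataset(strong_cohort())
corr = correlate_features(ds)
corr.to_csv(RESULTS / "correlations.csv", index=False, float_format="%.6g")
table = render_table_correlations(corr)
(RESULTS / "correlations_table.md").write_text(to_markdown(table))

sig = corr[corr["p"] < 0.05]
print(f"{len(corr)} features screened over {len(ds)} days; "
      f"{len(sig)} significant at p<0.05")
print(table.head(12).to_string(index=False))
print(f"wrote {RESULTS / 'correlations.csv'}")
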