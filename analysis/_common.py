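"""Shared study conditions for the numbered analysis scripts.

The primary analysis cohort is the strong-coupling preset at the study's
design size (10 patients, 30 days — two ~15-day chemotherapy cycles of
usable data per patient); the null cohort is the matching uncoupled
control. All scripts regenerate cohorts deterministically from these
seeds, so any script can be run on its own.
"""

from pathlib import Path

from symburden.synthetic import generate_cohort, null_preset, strong_preset

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

N_PATIENTS = 10
DAYS = 30
STRONG_SEED = 3
NULL_SEED = 101
EVAL_SEED = 4


def strong_cohort():
    return generate_cohort(strong_preset(N_PATIENTS, DAYS, seed=STRONG_SEED))


def null_cohort():
    return generate_cohort(null_preset(N_PATIENTS, DAYS, seed=NULL_SEED))


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
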