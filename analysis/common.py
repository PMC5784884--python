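"""Shared plumbing for the numbered analysis drivers.

Every driver works from the same demonstration configuration (seed 0):
small synthetic cohorts with AD-like effects planted on four
sphingolipid-analog metabolites, sized to run in seconds. Stage inputs are
read back from the previous stage's ``results/`` directory where a
plain-text representation exists; log-scale matrices are re-derived from
the raw cohorts through the library's preprocessing chain.
"""

from pathlib import Path

from easead.io import read_cohort
from easead.pipeline import (
    _preprocess_brain,
    _preprocess_serum,
    demo_pipeline_config,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "01_cohorts"

SEED = 0
CONFIG = demo_pipeline_config(SEED)
PLANTED = [f"SM{i:03d}" for i in (1, 2, 3, 4)]


def load_raw_cohorts():
    return {name: read_cohort(COHORT_DIR / name)
            for name in ("brain", "preclinical", "prodromal")}


def load_processed_cohorts():
    raw = load_raw_cohorts()
    modes = CONFIG.impute_modes
    return {
        "brain": _preprocess_brain(raw["brain"], modes["brain"]),
        "preclinical": _preprocess_serum(
            raw["preclinical"], modes["preclinical"], CONFIG.metso_threshold, True),
        "prodromal": _preprocess_serum(
            raw["prodromal"], modes["prodromal"], CONFIG.metso_threshold, False),
    }
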