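"""Domain-specific composite cognitive scores.

Raw neuropsychological test scores are standardized against the cohort's
baseline (time = 0) visit, oriented so that higher always means better, and
averaged within domain (memory, attention, executive, language,
visuospatial). Records after estimated symptom onset are removed for
converters so trajectory models see only the preclinical phase.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .battery import DOMAINS


def build_composites(
    visits: pd.DataFrame,
    domain_map: Mapping[str, str],
    orientation_map: Mapping[str, bool],
    standardize_on: str = "all",
) -> pd.DataFrame:
    """Turn long-format raw test scores into per-visit domain composites.

    Each test is z-scored against the baseline mean/SD of the
    standardization cohort; tests where a higher raw score is worse (timed
    tests) are negated before z-scoring; the composite is the mean of the
    available constituent z-scores.

    Parameters
    ----------
    visits
        Long format: ``subject_id``, ``time_days``, ``test_name``, ``score``.
    domain_map
        test name -> domain; every test must map to exactly one domain.
    orientation_map
        test name -> True if higher raw score is better.
    standardize_on
        ``"all"`` uses every subject's baseline visit (the default — the only
        population guaranteed observed at time 0).

    Returns
    -------
    Wide frame: one row per (subject, visit time), one column per domain,
    NaN where no constituent test was observed.
    """
    unknown = set(visits["test_name"]) - set(domain_map)
    if unknown:
        raise ValueError(f"tests missing from domain_map: {sorted(unknown)}")
    if standardize_on != "all":
        raise ValueError(f"unknown standardization population: {standardize_on!r}")

    df = visits.copy()
    orient = df["test_name"].map(lambda t: 1.0 if orientation_map[t] else -1.0)
    df["oriented"] = df["score"].to_numpy(dtype=float) * orient.to_numpy()

    base = df[df["time_days"] == 0]
    stats = base.groupby("test_name")["oriented"].agg(["mean", "std"])
    zero_sd = stats.index[(stats["std"] == 0) | stats["std"].isna()]
    if len(zero_sd):
        raise ValueError(f"zero baseline SD for tests: {list(zero_sd)}")
    df["z"] = (
        (df["oriented"] - df["test_name"].map(stats["mean"]).to_numpy())
        / df["test_name"].map(stats["std"]).to_numpy()
    )
    df["domain"] = df["test_name"].map(domain_map)
    wide = (
        df.groupby(["subject_id", "time_days", "domain"])["z"].mean()
        .unstack("domain")
        .reindex(columns=list(DOMAINS))
        .reset_index()
    )
    return wide


def truncate_post_onset(
    visits: pd.DataFrame,
    onset_age: pd.Series,
    baseline_age: pd.Series,
) -> pd.DataFrame:
    """Drop visits strictly after estimated AD symptom onset.

    Non-converters (NaN onset) keep every visit. A visit exactly at onset is
    retained (the onset visit may itself have informed the onset estimate).
    An onset before baseline is degenerate: a warning-level flag is implied
    and every post-baseline visit of that subject is removed.

    Parameters
    ----------
    visits
        Any frame with ``subject_id`` and ``time_days`` columns.
    onset_age, baseline_age
        Per-subject series indexed by subject_id; onset NaN for non-converters.
    """
    subj = visits["subject_id"]
    onset = onset_age.reindex(subj).to_numpy(dtype=float)
    base = baseline_age.reindex(subj).to_numpy(dtype=float)
    visit_age = base + visits["time_days"].to_numpy(dtype=float) / 365.25
    keep = np.isnan(onset) | (visit_age <= onset + 1e-9)
    # degenerate onsets before baseline: keep exactly the baseline visit
    degenerate = ~np.isnan(onset) & (onset < base)
    at_baseline = visits["time_days"].to_numpy(dtype=float) == 0
    keep = np.where(degenerate, at_baseline, keep)
    return visits.loc[keep].reset_index(drop=True)
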