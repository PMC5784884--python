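"""Quality control and normalization of concentration tables.

Implements the serum-quality exclusion on methionine sulfoxide (Met-So), the
two limit-of-detection (LOD) imputation dialects used for brain vs. blood
matrices, duplicate-measurement averaging, the natural-log transform applied
before every model fit, and storage-time matching of converter /
non-converter samples for sensitivity analyses.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .containers import ConcentrationMatrix

ImputeMode = Literal["highest_below_lod", "half_lod", "none"]

#: Default LOD handling per cohort. Brain tissue censors are set to the highest
#: observed sub-LOD value (removes sub-LOD differences while keeping the
#: above/below contrast); preclinical serum is left unimputed (minimal
#: missingness); prodromal serum uses the conventional LOD/2 substitution.
DEFAULT_IMPUTE_MODE = {
    "brain": "highest_below_lod",
    "preclinical": "none",
    "prodromal": "half_lod",
}


def filter_metso(
    metadata: pd.DataFrame,
    threshold: float = 5.0,
    mode: Literal["fixed", "mean_3sd"] = "fixed",
) -> tuple[list, list]:
    """Split blood samples into retained / excluded by Met-So concentration.

    Met-So, an oxidation product of methionine, rises with sample degradation
    and is used as a serum-quality indicator; samples strictly above the
    threshold (default 5 μM) are excluded.

    Parameters
    ----------
    metadata
        Must contain ``sample_id`` and ``metso`` columns.
    threshold
        Cutoff in μM; exclusion is strict (``metso > threshold``).
    mode
        ``"fixed"`` uses ``threshold`` as-is; ``"mean_3sd"`` recomputes the
        cutoff as mean + 3·SD of the supplied samples.

    Returns
    -------
    (retained_ids, excluded_ids)
        Sample-id lists, both in input order; their union is the input.
    """
    metso = metadata["metso"]
    if metso.isna().any():
        bad = metadata.loc[metso.isna(), "sample_id"].tolist()
        raise ValueError(f"missing Met-So value for samples: {bad}")
    if mode == "mean_3sd":
        threshold = float(metso.mean() + 3.0 * metso.std(ddof=1))
    elif mode != "fixed":
        raise ValueError(f"unknown Met-So threshold mode: {mode!r}")
    excl = metso > threshold
    return (
        metadata.loc[~excl, "sample_id"].tolist(),
        metadata.loc[excl, "sample_id"].tolist(),
    )


def impute_lod(matrix: ConcentrationMatrix, mode: ImputeMode) -> ConcentrationMatrix:
    """Impute below-LOD cells according to the requested dialect.

    ``highest_below_lod``
        Per metabolite, every censored cell becomes the maximum raw value
        among that metabolite's censored cells (falling back to the LOD
        itself when no raw value was recorded).
    ``half_lod``
        Every censored cell becomes LOD/2.
    ``none``
        Returns an unmodified copy.

    Cells above the LOD are never changed.
    """
    out = matrix.copy()
    if mode == "none":
        return out
    if mode not in ("highest_below_lod", "half_lod"):
        raise ValueError(f"unknown imputation mode: {mode!r}")
    vals = out.values
    flags = out.below_lod
    for met in vals.columns:
        mask = flags[met].to_numpy()
        if not mask.any():
            continue
        if mode == "half_lod":
            fill = out.lod[met] / 2.0
        else:
            raw = vals.loc[mask, met]
            fill = float(raw.max()) if raw.notna().any() else float(out.lod[met])
        vals.loc[mask, met] = fill
    return out


def average_duplicates(
    matrix: ConcentrationMatrix, metadata: pd.DataFrame
) -> tuple[ConcentrationMatrix, pd.DataFrame]:
    """Average replicate measurements so each subject contributes one row.

    Replicates are rows of ``matrix`` whose samples share a ``subject_id``.
    Values are averaged arithmetically per metabolite; a cell stays flagged
    below-LOD only when *all* replicates were censored. Metadata keeps the
    first replicate's covariates, re-keyed to one sample per subject.
    """
    meta = metadata.set_index("sample_id").loc[matrix.sample_ids]
    meta.index.name = "sample_id"
    subj = meta["subject_id"]
    if meta.groupby("subject_id")["cohort"].nunique().max() > 1:
        raise ValueError("duplicate measurements span different cohorts")
    if subj.is_unique:
        return matrix.copy(), metadata.copy()
    values = matrix.values.groupby(subj.to_numpy()).mean()
    flags = matrix.below_lod.groupby(subj.to_numpy()).all()
    first = meta.reset_index().groupby("subject_id", sort=False).first().reset_index()
    order = first["subject_id"].tolist()
    values = values.loc[order]
    flags = flags.loc[order]
    new_ids = first["sample_id"]
    values.index = new_ids.to_numpy()
    flags.index = new_ids.to_numpy()
    out = ConcentrationMatrix(values, flags, matrix.lod.copy(), matrix.families.copy())
    return out, first[metadata.columns]


def log_transform(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Natural-log transform every concentration (run after imputation)."""
    arr = matrix.values.to_numpy(dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "nonpositive concentration at sample "
            f"{matrix.sample_ids[i]!r}, metabolite {matrix.metabolite_ids[j]!r}"
        )
    out = matrix.copy()
    out.values = np.log(out.values)
    return out


def match_storage_time(
    converters: pd.DataFrame,
    non_converters: pd.DataFrame,
    tolerance: float = 2.0,
) -> list[tuple]:
    """Pair converters to non-converters on serum storage time within ±tolerance.

    Uses maximum bipartite matching (Hopcroft–Karp) on the graph connecting
    samples whose storage-time difference is at most ``tolerance`` years, so
    the number of retained pairs is the maximum achievable. Output is
    deterministic given input order.

    Parameters
    ----------
    converters, non_converters
        Frames with ``sample_id`` and ``storage_time`` columns.

    Returns
    -------
    list of (converter_sample_id, non_converter_sample_id) pairs.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    ct = converters["storage_time"].to_numpy(dtype=float)
    nt = non_converters["storage_time"].to_numpy(dtype=float)
    adj = np.abs(ct[:, None] - nt[None, :]) <= tolerance
    if not adj.any():
        return []
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    pairs = []
    cid = converters["sample_id"].to_numpy()
    nid = non_converters["sample_id"].to_numpy()
    for i, j in enumerate(match):
        if j >= 0:
            pairs.append((cid[i], nid[j]))
    return pairs


def preprocess_blood(
    matrix: ConcentrationMatrix,
    metadata: pd.DataFrame,
    impute_mode: ImputeMode,
    metso_threshold: float = 5.0,
) -> tuple[ConcentrationMatrix, pd.DataFrame]:
    """Standard serum QC chain: Met-So filter → duplicate averaging → LOD imputation → ln."""
    retained, _ = filter_metso(metadata, threshold=metso_threshold)
    keep = metadata["sample_id"].isin(retained)
    meta = metadata.loc[keep].reset_index(drop=True)
    sub = ConcentrationMatrix(
        matrix.values.loc[meta["sample_id"]],
        matrix.below_lod.loc[meta["sample_id"]],
        matrix.lod.copy(),
        matrix.families.copy(),
    )
    sub, meta = average_duplicates(sub, meta)
    sub = impute_lod(sub, impute_mode)
    return log_transform(sub), meta
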