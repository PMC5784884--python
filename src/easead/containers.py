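"""Core in-memory containers shared by every pipeline stage.

Concentrations are absolute values in micromolar (μM), as produced by a
targeted flow-injection / LC-MS/MS assay: one row per sample, one column per
metabolite, with a per-cell below-limit-of-detection (LOD) flag and a
per-metabolite LOD. Sample-level covariates travel in a plain
:class:`pandas.DataFrame` with a fixed column schema (:data:`METADATA_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Metabolite family labels used by the panel (mirrors a targeted p180-style assay).
FAMILIES = (
    "acylcarnitine",
    "amino acid",
    "biogenic amine",
    "glycerophospholipid",
    "sphingolipid",
    "hexose",
)

#: Required metadata columns. ``region`` is "none" for blood samples;
#: ``metso`` / ``storage_time`` are NaN for brain tissue samples.
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "cohort",
    "group",
    "region",
    "age",
    "sex",
    "storage_time",
    "metso",
)

BRAIN_REGIONS = ("MFG", "ITG", "CBL")


@dataclass
class ConcentrationMatrix:
    """Samples × metabolites concentration table in μM.

    Parameters
    ----------
    values
        Nonnegative concentrations; index = sample ids, columns = metabolite ids.
    below_lod
        Boolean frame aligned with ``values``; True marks a censored cell.
    lod
        Per-metabolite limit of detection in μM (index = metabolite ids).
    families
        Per-metabolite family annotation (index = metabolite ids).
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    lod: pd.Series
    families: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.families is None:
            self.families = pd.Series("unknown", index=self.values.columns)
        self.validate()

    # -- basic protocol -----------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values.copy(), self.below_lod.copy(), self.lod.copy(), self.families.copy()
        )

    def validate(self) -> None:
        v, b = self.values, self.below_lod
        if not (v.index.equals(b.index) and v.columns.equals(b.columns)):
            raise ValueError("values and below_lod are not aligned")
        if not v.columns.equals(self.lod.index):
            raise ValueError("lod index does not match metabolite columns")
        if not v.columns.equals(self.families.index):
            raise ValueError("families index does not match metabolite columns")
        arr = v.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("negative concentration encountered")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.values.shape
        return f"ConcentrationMatrix({n} samples × {p} metabolites)"


def validate_metadata(metadata: pd.DataFrame) -> None:
    """Check the fixed metadata schema and cohort-specific invariants."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    brain = metadata["cohort"] == "brain"
    if brain.any() and (metadata.loc[brain, "region"] == "none").any():
        raise ValueError("brain samples must carry a region")
    blood = ~brain
    if blood.any():
        bad = metadata.loc[blood, "metso"].isna() | metadata.loc[blood, "storage_time"].isna()
        if bad.any():
            raise ValueError(
                "blood samples missing metso/storage_time: "
                f"{metadata.loc[blood].loc[bad, 'sample_id'].tolist()}"
            )
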