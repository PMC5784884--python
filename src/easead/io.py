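"""Plain-text table readers/writers (UTF-8 TSV, empty string for missing).

A concentration matrix is stored as three companion files sharing a stem:
``<stem>.tsv`` (wide values, one row per sample), ``<stem>_lodflags.tsv``
(0/1 censoring flags with the same shape) and ``<stem>_lod.tsv`` (one row
per metabolite: LOD in μM and family annotation).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ConcentrationMatrix


def write_concentrations(matrix: ConcentrationMatrix, stem) -> None:
    stem = Path(stem)
    matrix.values.to_csv(stem.with_suffix(".tsv"), sep="\t", index_label="sample_id")
    matrix.below_lod.astype(int).to_csv(
        _flags_path(stem), sep="\t", index_label="sample_id")
    pd.DataFrame({"lod": matrix.lod, "family": matrix.families}).to_csv(
        _lod_path(stem), sep="\t", index_label="metabolite")


def read_concentrations(stem) -> ConcentrationMatrix:
    stem = Path(stem)
    values = pd.read_csv(stem.with_suffix(".tsv"), sep="\t", index_col="sample_id")
    flags = pd.read_csv(_flags_path(stem), sep="\t", index_col="sample_id").astype(bool)
    lodtab = pd.read_csv(_lod_path(stem), sep="\t", index_col="metabolite")
    return ConcentrationMatrix(values, flags, lodtab["lod"], lodtab["family"])


def _flags_path(stem: Path) -> Path:
    return stem.with_name(stem.name + "_lodflags.tsv")


def _lod_path(stem: Path) -> Path:
    return stem.with_name(stem.name + "_lod.tsv")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# whole-cohort round trip
# ---------------------------------------------------------------------------
_OPTIONAL_FRAMES = ("neuropath", "survival", "visits", "xsect")


def write_cohort(cohort, directory) -> None:
    """Write a cohort bundle as plain TSVs plus the truth parameters as YAML."""
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    conc = cohort.concentrations
    if isinstance(conc, dict):
        for region, mat in conc.items():
            write_concentrations(mat, directory / f"concentrations_{region}")
    else:
        write_concentrations(conc, directory / "concentrations")
    write_table(cohort.metadata, directory / "metadata.tsv")
    for name in _OPTIONAL_FRAMES:
        frame = getattr(cohort, name)
        if frame is not None:
            write_table(frame, directory / f"{name}.tsv")
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(_yaml_safe(cohort.truth), fh, sort_keys=True)


def read_cohort(directory):
    """Inverse of :func:`write_cohort`."""
    import yaml

    from .synthetic import SyntheticCohort

    directory = Path(directory)
    region_stems = sorted(directory.glob("concentrations_*_lod.tsv"))
    if region_stems:
        conc = {}
        for lodfile in region_stems:
            region = lodfile.name[len("concentrations_"):-len("_lod.tsv")]
            conc[region] = read_concentrations(directory / f"concentrations_{region}")
    else:
        conc = read_concentrations(directory / "concentrations")
    frames = {}
    for name in _OPTIONAL_FRAMES:
        path = directory / f"{name}.tsv"
        frames[name] = read_table(path) if path.exists() else None
    with open(directory / "truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    return SyntheticCohort(
        conc, read_table(directory / "metadata.tsv"), truth=truth, **frames)


def _yaml_safe(obj):
    """Recursively coerce numpy scalars/containers to plain Python types."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
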