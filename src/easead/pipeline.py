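"""End-to-end orchestration: simulate → preprocess → discover → score.

:func:`run_full` drives the whole pipeline from one configuration object and
one master seed, writes every intermediate table as TSV plus a run manifest,
and returns the in-memory bundle. Re-running with the same configuration
reproduces the outputs byte-identically.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .battery import results_to_frame, run_battery
from .composites import build_composites, truncate_post_onset
from .containers import BRAIN_REGIONS, ConcentrationMatrix
from .discovery import ClassifierSpec, build_panel, loo_evaluate, rank_rf, rank_svm, select_region
from .io import write_concentrations, write_table
from .preprocess import DEFAULT_IMPUTE_MODE, impute_lod, log_transform, preprocess_blood
from .scoring import EaseAdTable, PolarityMap, compute_ease_ad, write_heatmap_tsv
from .synthetic import (
    DOMAIN_MAP,
    ORIENTATION_MAP,
    SyntheticCohort,
    SyntheticConfig,
    generate_brain_cohort,
    generate_preclinical_cohort,
    generate_prodromal_cohort,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with one master seed."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    impute_modes: dict = field(default_factory=lambda: dict(DEFAULT_IMPUTE_MODE))
    metso_threshold: float = 5.0
    k: int = 20
    svm_n_selected: int = 20
    svm_C: float = 1.0
    rf_n_trees: int = 500
    rf_n_permutations: int = 10
    alpha: float = 0.05
    region_mode: str = "auto"        # "auto" or a fixed region name
    include_prodromal: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.synthetic = (
            self.synthetic if isinstance(self.synthetic, SyntheticConfig)
            else SyntheticConfig(**self.synthetic)
        )
        # master seed fans out; the synthetic config carries the same seed
        self.synthetic = replace(self.synthetic, seed=self.seed)
        if self.region_mode != "auto" and self.region_mode not in BRAIN_REGIONS:
            raise ValueError(f"unknown region_mode {self.region_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def demo_pipeline_config(seed: int = 0) -> PipelineConfig:
    """Small synthetic configuration with AD-like effects planted on
    sphingolipid-analog metabolites, sized to run in seconds."""
    planted_sm = [f"SM{i:03d}" for i in (1, 2, 3, 4)]
    synth = SyntheticConfig(
        n_metabolites=40,
        family_composition={
            "acylcarnitine": 6, "amino acid": 5, "biogenic amine": 5,
            "glycerophospholipid": 15, "sphingolipid": 8, "hexose": 1,
        },
        preclinical_group_sizes={"converter": 60, "non-converter": 60},
        prodromal_group_sizes={"CN": 60, "MCI": 90, "AD": 50},
        planted_brain_effects={m: ("ITG", 1.6, 0.5) for m in planted_sm},
        planted_log_hr={m: np.log(2.0) for m in planted_sm},
        planted_traj_slope={m: -0.10 for m in planted_sm},
        planted_xsect_beta={
            m: [("spare_ad", 0.6), ("ttau", 0.25), ("ptau", 0.25), ("abeta", -0.15)]
            for m in planted_sm
        },
        seed=seed,
    )
    return PipelineConfig(
        synthetic=synth, k=10, svm_n_selected=10,
        rf_n_trees=150, rf_n_permutations=5, seed=seed,
    )


def _preprocess_brain(cohort: SyntheticCohort, mode: str) -> SyntheticCohort:
    mats = {r: log_transform(impute_lod(m, mode)) for r, m in cohort.concentrations.items()}
    return SyntheticCohort(mats, cohort.metadata, neuropath=cohort.neuropath,
                           truth=cohort.truth)


def _preprocess_serum(cohort: SyntheticCohort, mode: str, metso_threshold: float,
                      with_visits: bool) -> SyntheticCohort:
    matrix, meta = preprocess_blood(
        cohort.concentrations, cohort.metadata, mode, metso_threshold)
    keep = set(meta["subject_id"])
    surv = cohort.survival[cohort.survival["subject_id"].isin(keep)].reset_index(drop=True)
    visits = xsect = None
    if with_visits and cohort.visits is not None:
        raw = cohort.visits[cohort.visits["subject_id"].isin(keep)]
        comps = build_composites(raw, DOMAIN_MAP, ORIENTATION_MAP)
        onset = meta.set_index("subject_id")["onset_age"]
        base_age = meta.set_index("subject_id")["age"]
        visits = truncate_post_onset(comps, onset, base_age)
    if cohort.xsect is not None:
        xsect = cohort.xsect[cohort.xsect["subject_id"].isin(keep)].reset_index(drop=True)
    return SyntheticCohort(matrix, meta, survival=surv, visits=visits,
                           xsect=xsect, truth=cohort.truth)


def run_full(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the output bundle.

    Bundle keys: ``panel``, ``region``, ``metrics``, ``results`` (long
    results frame), ``table`` (:class:`EaseAdTable`) and the processed
    cohorts. When ``out_dir`` is set, every intermediate table is written as
    TSV along with ``run_manifest.yaml``.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, err) from err

    synth = config.synthetic
    brain_raw = stage("simulate", lambda: generate_brain_cohort(synth))
    precl_raw = stage("simulate", lambda: generate_preclinical_cohort(synth))
    prodr_raw = (stage("simulate", lambda: generate_prodromal_cohort(synth))
                 if config.include_prodromal else None)

    brain = stage("preprocess", lambda: _preprocess_brain(
        brain_raw, config.impute_modes["brain"]))
    precl = stage("preprocess", lambda: _preprocess_serum(
        precl_raw, config.impute_modes["preclinical"], config.metso_threshold, True))
    prodr = (stage("preprocess", lambda: _preprocess_serum(
        prodr_raw, config.impute_modes["prodromal"], config.metso_threshold, False))
        if prodr_raw is not None else None)

    # --- discovery on AD vs CN brain samples ------------------------------
    def discover():
        meta = brain.metadata
        metrics, loos = {}, {}
        svm_spec = ClassifierSpec("svm", n_selected=config.svm_n_selected, C=config.svm_C)
        rf_spec = ClassifierSpec("rf", n_trees=config.rf_n_trees)
        for region, mat in brain.concentrations.items():
            sel = meta[(meta["region"] == region) & meta["group"].isin(["AD", "CN"])]
            X = mat.values.loc[sel["sample_id"]]
            y = sel["group"].to_numpy()
            loo_svm = loo_evaluate(X, y, svm_spec, seed=config.seed)
            loo_rf = loo_evaluate(X, y, rf_spec, seed=config.seed)
            metrics[region] = {"svm": loo_svm.metrics, "rf": loo_rf.metrics}
            loos[region] = (loo_svm, X, y)
        region = (select_region(metrics) if config.region_mode == "auto"
                  else config.region_mode)
        loo_svm, X, y = loos[region]
        svm_list = rank_svm(loo_svm, all_metabolites=X.columns)
        rf_list = rank_rf(X, y, n_trees=config.rf_n_trees,
                          n_permutations=config.rf_n_permutations, seed=config.seed)
        panel = build_panel(svm_list, rf_list, k=config.k)
        return region, metrics, svm_list, rf_list, panel

    region, metrics, svm_list, rf_list, panel = stage("discover", discover)

    results = stage("battery", lambda: run_battery(
        panel.panel, brain=brain, preclinical=precl, prodromal=prodr,
        alpha=config.alpha, region=region))
    res_frame = results_to_frame(results, alpha=config.alpha)
    families = brain.concentrations[region].families
    table = stage("score", lambda: compute_ease_ad(
        results, PolarityMap(), alpha=config.alpha, families=families))

    if out:
        stage("write", lambda: _write_outputs(
            out, config, region, metrics, svm_list, rf_list, panel,
            res_frame, table, brain, precl, prodr))
    return {
        "region": region, "metrics": metrics, "svm": svm_list, "rf": rf_list,
        "panel": panel, "results": res_frame, "table": table,
        "brain": brain, "preclinical": precl, "prodromal": prodr,
    }


def _write_outputs(out, config, region, metrics, svm_list, rf_list, panel,
                   res_frame, table, brain, precl, prodr):
    for r, mat in brain.concentrations.items():
        write_concentrations(mat, out / f"brain_{r}")
    write_table(brain.metadata, out / "brain_metadata.tsv")
    write_concentrations(precl.concentrations, out / "preclinical")
    write_table(precl.metadata, out / "preclinical_metadata.tsv")
    if prodr is not None:
        write_concentrations(prodr.concentrations, out / "prodromal")
        write_table(prodr.metadata, out / "prodromal_metadata.tsv")
    ranked = pd.concat([
        pd.DataFrame(
            [(i + 1, m, s, lst.classifier) for i, (m, s) in enumerate(lst.entries)],
            columns=["rank", "metabolite", "score", "classifier"])
        for lst in (svm_list, rf_list)
    ])
    write_table(ranked, out / "ranked_lists.tsv")
    (out / "panel.txt").write_text("\n".join(panel.panel) + "\n")
    write_table(res_frame, out / "battery_results.tsv")
    write_heatmap_tsv(table, out / "ease_ad_heatmap.tsv")
    pvals = res_frame.pivot_table(
        index="metabolite", columns="category", values="p", aggfunc="min")
    pvals.to_csv(out / "ease_ad_pvalues.tsv", sep="\t")
    metric_rows = [
        {"region": r, "classifier": c, "accuracy": m.accuracy,
         "sensitivity": m.sensitivity, "specificity": m.specificity}
        for r, ms in metrics.items() for c, m in ms.items()
    ]
    write_table(pd.DataFrame(metric_rows), out / "loo_metrics.tsv")
    manifest = {
        "easead_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "selected_region": region,
        "panel_size": len(panel.panel),
        "alpha": config.alpha,
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
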