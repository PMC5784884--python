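"""Synthetic brain and blood cohorts with planted, recoverable effects.

Three generators mirror the three study designs the pipeline analyses:

``generate_brain_cohort``
    An autopsy cohort (AD / CN / ASYMAD) with one concentration matrix per
    brain region (MFG, ITG, CBL), Gaussian log-concentrations, group mean
    shifts confined to a single configured region, ordinal neuropathology
    scores (CERAD 0–3, Braak 0–6) monotone in an underlying severity latent,
    and limit-of-detection censoring.

``generate_preclinical_cohort``
    A serum cohort of cognitively normal older adults followed for
    conversion to incident AD: exponential proportional-hazards conversion
    times driven by planted log hazard ratios, biennial cognitive visits
    with raw test scores whose annualized slopes respond to planted
    metabolite effects, Met-So contamination, and a storage-time imbalance
    between converters and non-converters.

``generate_prodromal_cohort``
    A CN/MCI/AD serum cohort with a cross-sectional MRI atrophy index
    (SPARE-AD) and CSF markers (Aβ1–42, t-tau, p-tau) generated as linear
    functions of log concentrations, and MCI → AD conversion times.

One global seed fans out into fixed, named substreams so adding a stream
never perturbs another; identical (config, seed) gives identical cohorts.
The generators plant effects but make no attempt to match real cohorts'
marginal distributions or inter-metabolite correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import BRAIN_REGIONS, ConcentrationMatrix

# fixed substream ids: adding a new stream appends, never renumbers
_STREAMS = {
    "brain_base": 1,
    "brain_conc": 2,
    "brain_meta": 3,
    "brain_neuropath": 4,
    "blood_base": 11,
    "blood_conc": 12,
    "blood_meta": 13,
    "blood_survival": 14,
    "blood_visits": 15,
    "blood_metso": 16,
    "adni_base": 21,
    "adni_conc": 22,
    "adni_meta": 23,
    "adni_xsect": 24,
    "adni_survival": 25,
}

#: Raw cognitive tests: name -> (domain, baseline mean, baseline SD, higher_is_better).
#: Timed trail-making tests are worse-is-higher; everything else better-is-higher.
COGNITIVE_TESTS = {
    "cvlt_learning": ("memory", 50.0, 10.0, True),
    "cvlt_immediate_recall": ("memory", 11.0, 3.0, True),
    "cvlt_delayed_recall": ("memory", 10.0, 3.0, True),
    "trails_a": ("attention", 35.0, 12.0, False),
    "digits_forward": ("attention", 8.0, 2.0, True),
    "trails_b": ("executive", 90.0, 40.0, False),
    "digits_backward": ("executive", 6.0, 2.0, True),
    "letter_fluency": ("language", 13.0, 4.0, True),
    "semantic_fluency": ("language", 17.0, 5.0, True),
    "clock_drawing": ("visuospatial", 9.0, 1.5, True),
    "card_rotation": ("visuospatial", 60.0, 20.0, True),
}

DOMAIN_MAP = {t: v[0] for t, v in COGNITIVE_TESTS.items()}
ORIENTATION_MAP = {t: v[3] for t, v in COGNITIVE_TESTS.items()}

#: Per-test residual SD on the latent z scale.
_COG_TEST_NOISE = 0.3

XSECT_ENDOPHENOTYPES = ("spare_ad", "abeta", "ttau", "ptau")
_XSECT_ALIASES = {"SPARE-AD": "spare_ad", "spare-ad": "spare_ad"}

_FAMILY_PREFIX = {
    "acylcarnitine": "AC",
    "amino acid": "AA",
    "biogenic amine": "BA",
    "glycerophospholipid": "PC",
    "sphingolipid": "SM",
    "hexose": "H",
}


@dataclass
class SyntheticConfig:
    """Generative counterpart of the three study designs.

    Planted-effect mappings are empty by default (a global null). Sample
    sizes default to the study designs: 15/14/15 AD/CN/ASYMAD brains, 250
    serum samples pre-exclusion split into converter/non-converter targets,
    and 216/366/185 CN/MCI/AD prodromal samples.
    """

    n_metabolites: int = 187
    family_composition: dict = field(default_factory=lambda: {
        "acylcarnitine": 40, "amino acid": 21, "biogenic amine": 21,
        "glycerophospholipid": 89, "sphingolipid": 15, "hexose": 1,
    })
    group_sizes: dict = field(default_factory=lambda: {"AD": 15, "CN": 14, "ASYMAD": 15})
    preclinical_group_sizes: dict = field(default_factory=lambda: {
        "converter": 126, "non-converter": 124})
    prodromal_group_sizes: dict = field(default_factory=lambda: {
        "CN": 216, "MCI": 366, "AD": 185})
    #: metabolite -> (region, standardized AD−CN mean shift, ASYMAD fraction in [0,1])
    planted_brain_effects: dict = field(default_factory=dict)
    #: metabolite -> log hazard ratio per 1 log-unit concentration
    planted_log_hr: dict = field(default_factory=dict)
    #: metabolite -> change in annualized cognitive slope (z/year) per log-unit
    planted_traj_slope: dict = field(default_factory=dict)
    #: metabolite -> (endophenotype, slope) or list thereof
    planted_xsect_beta: dict = field(default_factory=dict)
    lod_quantile: float = 0.05
    #: (fraction above 5 μM, mean exceedance above 5 μM); the fraction may be a
    #: per-group mapping, defaulting to the observed converter-skewed split.
    metso_contamination: tuple = (
        {"converter": 34 / 126, "non-converter": 9 / 124}, 2.0)
    storage_shift_years: float = 4.5
    censor_time: float = 10.0
    #: expected conversion fraction by censor_time at baseline covariates;
    #: sets the exponential baseline hazard (Cox estimation is baseline-free)
    conversion_fraction: float = 0.504
    mci_conversion_fraction: float = 0.40
    age_log_hr: float = 0.04
    visit_interval_years: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.family_composition.values()) != self.n_metabolites:
            raise ValueError("family_composition must sum to n_metabolites")
        for name, sizes in (("group_sizes", self.group_sizes),
                            ("preclinical_group_sizes", self.preclinical_group_sizes),
                            ("prodromal_group_sizes", self.prodromal_group_sizes)):
            if any(v <= 0 for v in sizes.values()):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must be in [0, 1)")

    def metabolite_ids(self) -> tuple[list[str], pd.Series]:
        ids, fams = [], []
        for fam in sorted(self.family_composition):
            count = self.family_composition[fam]
            prefix = _FAMILY_PREFIX.get(fam, fam[:2].upper())
            for i in range(count):
                ids.append(f"{prefix}{i + 1:03d}" if count > 1 else f"{prefix}1")
                fams.append(fam)
        return ids, pd.Series(fams, index=ids, name="family")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))

    def truth(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """One generated cohort plus the planted ground truth."""

    concentrations: object            # ConcentrationMatrix, or region -> matrix
    metadata: pd.DataFrame
    neuropath: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    visits: pd.DataFrame | None = None
    xsect: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _baseline_params(rng: np.random.Generator, p: int):
    """Per-metabolite log-scale mean and SD of the concentration distribution."""
    mu = rng.normal(1.0, 0.8, p)
    sigma = rng.uniform(0.25, 0.6, p)
    return mu, sigma


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _apply_lod(values: pd.DataFrame, quantile: float):
    """Per-metabolite LOD at the given marginal quantile; strictly-below flagged."""
    if quantile <= 0:
        lod = values.min(axis=0) * 0.0
    else:
        lod = values.quantile(quantile, axis=0)
    flags = values.lt(lod, axis=1)
    return flags, lod


# ---------------------------------------------------------------------------
# brain cohort
# ---------------------------------------------------------------------------
def generate_brain_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Autopsy cohort: one matrix per region, shifts confined to one region."""
    if any(v < 2 for v in config.group_sizes.values()):
        raise ValueError("brain group sizes must be at least 2")
    ids, families = config.metabolite_ids()
    idx = {m: j for j, m in enumerate(ids)}
    for met, (region, _, frac) in config.planted_brain_effects.items():
        if region not in BRAIN_REGIONS:
            raise ValueError(f"unknown region {region!r} in planted effect for {met}")
        if met not in idx:
            raise ValueError(f"unknown metabolite {met!r} in planted_brain_effects")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("ASYMAD fraction must be in [0, 1]")
    p = config.n_metabolites
    mu, sigma = _baseline_params(config.rng("brain_base"), p)

    groups = [g for g in ("AD", "CN", "ASYMAD") if g in config.group_sizes]
    subjects, subj_group = [], []
    for g in groups:
        for i in range(config.group_sizes[g]):
            subjects.append(f"{g}{i + 1:02d}")
            subj_group.append(g)
    n = len(subjects)

    rng_c = config.rng("brain_conc")
    shift_mat = {r: np.zeros((3, p)) for r in BRAIN_REGIONS}  # rows: AD, CN, ASYMAD
    for met, (region, shift, frac) in config.planted_brain_effects.items():
        j = idx[met]
        shift_mat[region][0, j] = shift * sigma[j]          # AD − CN in log units
        shift_mat[region][2, j] = frac * shift * sigma[j]   # ASYMAD fraction of shift
    grp_row = {"AD": 0, "CN": 1, "ASYMAD": 2}

    matrices, sample_rows = {}, []
    rng_m = config.rng("brain_meta")
    age = _trunc_normal(rng_m, 81.0, 10.0, 60.0, 100.0, n)
    sex = rng_m.binomial(1, 0.36, n)
    pmi = _trunc_normal(rng_m, 15.0, 7.0, 2.0, 40.0, n)
    for region in BRAIN_REGIONS:
        region_offset = rng_c.normal(0.0, 0.1, p)
        z = rng_c.standard_normal((n, p))
        logc = mu + region_offset + sigma * z
        for i, g in enumerate(subj_group):
            logc[i] += shift_mat[region][grp_row[g]]
        sample_ids = [f"{s}_{region}" for s in subjects]
        values = pd.DataFrame(np.exp(logc), index=sample_ids, columns=ids)
        flags, lod = _apply_lod(values, config.lod_quantile)
        matrices[region] = ConcentrationMatrix(values, flags, lod, families.copy())
        for i, s in enumerate(subjects):
            sample_rows.append({
                "sample_id": sample_ids[i], "subject_id": s, "cohort": "brain",
                "group": subj_group[i], "region": region, "age": age[i],
                "sex": int(sex[i]), "storage_time": np.nan, "metso": np.nan,
                "postmortem_interval": pmi[i],
            })
    metadata = pd.DataFrame(sample_rows)

    # ordered latent severity, monotone in group: CN < ASYMAD <= AD
    rng_n = config.rng("brain_neuropath")
    base = {"CN": 0.0, "ASYMAD": 1.6, "AD": 2.0}
    latent = np.array([base[g] for g in subj_group]) + rng_n.normal(0.0, 0.6, n)
    cerad = np.digitize(latent, [0.5, 1.0, 1.6])
    braak = np.digitize(latent, [0.0, 0.4, 0.8, 1.2, 1.6, 2.0])
    neuropath = pd.DataFrame({
        "subject_id": subjects, "group": subj_group,
        "cerad": cerad.astype(int), "braak": braak.astype(int),
    })
    return SyntheticCohort(matrices, metadata, neuropath=neuropath, truth=config.truth())


# ---------------------------------------------------------------------------
# preclinical serum cohort
# ---------------------------------------------------------------------------
def _planted_linear_predictor(logc: pd.DataFrame, planted: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(logc))
    for met, coef in planted.items():
        if met not in logc.columns:
            raise ValueError(f"unknown metabolite {met!r} in planted mapping")
        col = logc[met].to_numpy()
        lp += coef * (col - col.mean())
    return lp


def generate_preclinical_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Serum cohort of cognitively normal adults followed for conversion."""
    if config.censor_time <= 0:
        raise ValueError("censor_time must be positive")
    ids, families = config.metabolite_ids()
    p = config.n_metabolites
    n = sum(config.preclinical_group_sizes.values())
    mu, sigma = _baseline_params(config.rng("blood_base"), p)

    rng_c = config.rng("blood_conc")
    logc = pd.DataFrame(
        mu + sigma * rng_c.standard_normal((n, p)),
        index=[f"P{i + 1:04d}" for i in range(n)], columns=ids)

    rng_m = config.rng("blood_meta")
    age = _trunc_normal(rng_m, 78.7, 7.2, 60.0, 98.0, n)
    sex = rng_m.binomial(1, 0.52, n)

    # exponential proportional hazards; baseline calibrated to the target
    # conversion fraction by the administrative censoring time
    rng_s = config.rng("blood_survival")
    lp = _planted_linear_predictor(logc, config.planted_log_hr)
    lp += config.age_log_hr * (age - age.mean())
    lam0 = -np.log(1.0 - config.conversion_fraction) / config.censor_time
    t_event = rng_s.exponential(1.0 / (lam0 * np.exp(lp)))
    event = t_event <= config.censor_time
    time = np.minimum(t_event, config.censor_time)
    group = np.where(event, "converter", "non-converter")

    storage = _trunc_normal(rng_m, 13.3, 6.0, 0.5, 30.0, n)
    storage = storage + np.where(event, config.storage_shift_years, 0.0)

    frac_spec, mean_excess = config.metso_contamination
    rng_q = config.rng("blood_metso")
    if isinstance(frac_spec, Mapping):
        frac = np.array([float(frac_spec.get(g, 0.0)) for g in group])
    else:
        frac = np.full(n, float(frac_spec))
    contaminated = rng_q.random(n) < frac
    metso = _trunc_normal(rng_q, 2.2, 0.9, 0.05, 4.99, n)
    metso[contaminated] = 5.0 + rng_q.exponential(mean_excess, contaminated.sum())

    sample_ids = logc.index
    metadata = pd.DataFrame({
        "sample_id": sample_ids, "subject_id": sample_ids,
        "cohort": "preclinical", "group": group, "region": "none",
        "age": age, "sex": sex.astype(int),
        "storage_time": storage, "metso": metso,
        "onset_age": np.where(event, age + t_event, np.nan),
    })
    survival = pd.DataFrame({
        "subject_id": sample_ids, "time": time, "event": event.astype(int)})

    # biennial cognitive visits with raw test scores; latent domain score is
    # z-scaled with subject random intercept and slope
    rng_v = config.rng("blood_visits")
    n_visits = int(np.floor(config.censor_time / config.visit_interval_years)) + 1
    visit_times = np.arange(n_visits) * config.visit_interval_years
    domains = sorted({d for d, *_ in COGNITIVE_TESTS.values()})
    slope_shift = _planted_linear_predictor(logc, config.planted_traj_slope)
    rows = []
    # baseline variance per test = intercept var + test noise var = 1, so the
    # latent z unit coincides with the composite's baseline-standardized unit
    # and planted slopes are recovered on their own scale
    b0 = rng_v.normal(0.0, np.sqrt(1.0 - _COG_TEST_NOISE ** 2), (n, len(domains)))
    b1 = rng_v.normal(0.0, 0.05, (n, len(domains)))
    base_slope = -0.03
    for vi, t in enumerate(visit_times):
        for di, dom in enumerate(domains):
            z_latent = b0[:, di] + (base_slope + slope_shift + b1[:, di]) * t
            for test, (d, m0, s0, higher_better) in COGNITIVE_TESTS.items():
                if d != dom:
                    continue
                eps = rng_v.normal(0.0, _COG_TEST_NOISE, n)
                zval = z_latent + eps
                score = m0 + s0 * (zval if higher_better else -zval)
                rows.append(pd.DataFrame({
                    "subject_id": sample_ids,
                    "time_days": t * 365.25,
                    "test_name": test,
                    "score": score,
                }))
    visits = pd.concat(rows, ignore_index=True)

    values = np.exp(logc)
    flags, lod = _apply_lod(values, config.lod_quantile)
    matrix = ConcentrationMatrix(values, flags, lod, families)
    return SyntheticCohort(
        matrix, metadata, survival=survival, visits=visits, truth=config.truth())


# ---------------------------------------------------------------------------
# prodromal serum cohort
# ---------------------------------------------------------------------------
def _normalize_xsect(planted: Mapping) -> dict[str, list[tuple[str, float]]]:
    out: dict[str, list[tuple[str, float]]] = {}
    for met, spec in planted.items():
        pairs = [spec] if isinstance(spec, tuple) else list(spec)
        for endo, slope in pairs:
            endo = _XSECT_ALIASES.get(endo, endo)
            if endo not in XSECT_ENDOPHENOTYPES:
                raise ValueError(
                    f"unknown endophenotype {endo!r} for {met}; "
                    f"expected one of {XSECT_ENDOPHENOTYPES}")
            out.setdefault(met, []).append((endo, float(slope)))
    return out


def generate_prodromal_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """CN/MCI/AD serum cohort with atrophy-index and CSF endophenotypes."""
    if config.censor_time <= 0:
        raise ValueError("censor_time must be positive")
    planted_x = _normalize_xsect(config.planted_xsect_beta)
    ids, families = config.metabolite_ids()
    p = config.n_metabolites
    sizes = config.prodromal_group_sizes
    groups = [g for g in ("CN", "MCI", "AD") if g in sizes]
    group = np.concatenate([[g] * sizes[g] for g in groups])
    n = len(group)
    mu, sigma = _baseline_params(config.rng("adni_base"), p)

    rng_c = config.rng("adni_conc")
    logc = pd.DataFrame(
        mu + sigma * rng_c.standard_normal((n, p)),
        index=[f"A{i + 1:04d}" for i in range(n)], columns=ids)

    rng_m = config.rng("adni_meta")
    age = _trunc_normal(rng_m, 75.2, 6.8, 55.0, 92.0, n)
    sex = rng_m.binomial(1, 0.43, n)
    metso = _trunc_normal(rng_m, 1.8, 0.7, 0.05, 4.99, n)
    storage = _trunc_normal(rng_m, 8.8, 0.4, 7.0, 10.5, n)

    # cross-sectional endophenotypes with the AD-like sign convention:
    # AD-like = higher atrophy index, higher t-tau/p-tau, lower Aβ1-42
    rng_x = config.rng("adni_xsect")
    betas = {e: np.zeros(n) for e in XSECT_ENDOPHENOTYPES}
    for met, pairs in planted_x.items():
        if met not in logc.columns:
            raise ValueError(f"unknown metabolite {met!r} in planted_xsect_beta")
        col = logc[met].to_numpy()
        for endo, slope in pairs:
            betas[endo] += slope * (col - col.mean())
    goff = {"CN": 0, "MCI": 1, "AD": 2}
    gi = np.array([goff[g] for g in group])
    spare = (np.array([-1.5, 0.3, 1.5])[gi] + betas["spare_ad"]
             + 0.03 * (age - 75.0) + 0.2 * sex + rng_x.normal(0.0, 1.0, n))
    ln_abeta = (np.log(170.0) + np.array([0.0, -0.15, -0.30])[gi] + betas["abeta"]
                - 0.004 * (age - 75.0) + rng_x.normal(0.0, 0.25, n))
    ln_ttau = (np.log(90.0) + np.array([0.0, 0.18, 0.35])[gi] + betas["ttau"]
               + 0.004 * (age - 75.0) + rng_x.normal(0.0, 0.30, n))
    ln_ptau = (np.log(30.0) + np.array([0.0, 0.18, 0.35])[gi] + betas["ptau"]
               + 0.004 * (age - 75.0) + rng_x.normal(0.0, 0.30, n))
    xsect = pd.DataFrame({
        "subject_id": logc.index, "spare_ad": spare,
        "abeta": np.exp(ln_abeta), "ttau": np.exp(ln_ttau), "ptau": np.exp(ln_ptau),
    })

    # MCI -> AD conversion, same proportional-hazards machinery
    rng_s = config.rng("adni_survival")
    mci = group == "MCI"
    lp = _planted_linear_predictor(logc, config.planted_log_hr)[mci]
    lp += config.age_log_hr * (age[mci] - age[mci].mean())
    lam0 = -np.log(1.0 - config.mci_conversion_fraction) / config.censor_time
    t_event = rng_s.exponential(1.0 / (lam0 * np.exp(lp)))
    event = t_event <= config.censor_time
    survival = pd.DataFrame({
        "subject_id": logc.index[mci],
        "time": np.minimum(t_event, config.censor_time),
        "event": event.astype(int),
    })

    metadata = pd.DataFrame({
        "sample_id": logc.index, "subject_id": logc.index,
        "cohort": "prodromal", "group": group, "region": "none",
        "age": age, "sex": sex.astype(int),
        "storage_time": storage, "metso": metso,
    })
    values = np.exp(logc)
    flags, lod = _apply_lod(values, config.lod_quantile)
    matrix = ConcentrationMatrix(values, flags, lod, families)
    return SyntheticCohort(
        matrix, metadata, survival=survival, xsect=xsect, truth=config.truth())
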