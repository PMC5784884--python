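"""The ten endophenotype association models, one uniform result per fit.

Every panel metabolite is tested against ten AD endophenotype categories:

========================  =====================================================
brain_group               proportional-odds group difference (AD/ASYMAD/CN) in
                          the signature region, ln brain concentration outcome
cerad / braak             covariate-adjusted Spearman correlation with neuritic
                          plaque (CERAD) / neurofibrillary tangle (Braak) scores
blsa_cox                  Cox PH: serum ln concentration vs. time to conversion
                          from normal cognition to incident AD
blsa_cognition            linear mixed model: metabolite × time interaction on
                          domain cognitive composites (converters, pre-onset)
spare_ad                  OLS: serum ln concentration vs. MRI atrophy index
csf_abeta/ttau/ptau       OLS on ln CSF marker concentrations
adni_cox                  Cox PH: MCI → incident AD conversion
========================  =====================================================

All models adjust for age and sex only; p-values are two-sided and
deliberately uncorrected (the panel is a fixed a-priori hypothesis set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as LifelinesConvergenceError
from scipy import stats

from .lmm import fit_random_slope
from .ordinal import ConvergenceError, fit_proportional_odds, null_loglik, score_test

#: Fixed category order (also the heat-map column order).
CATEGORIES = (
    "brain_group",
    "cerad",
    "braak",
    "blsa_cox",
    "blsa_cognition",
    "spare_ad",
    "csf_abeta",
    "csf_ttau",
    "csf_ptau",
    "adni_cox",
)

#: Fixed cognitive-domain order, used for deterministic tie-breaks.
DOMAINS = ("memory", "attention", "executive", "language", "visuospatial")


@dataclass
class EndophenotypeResult:
    """One (metabolite, endophenotype-category) association."""

    metabolite_id: str
    category: str
    estimate: float          # HR for Cox categories, β or ρ otherwise
    ci_low: float
    ci_high: float
    p: float
    n: int
    direction: str           # "increase" | "decrease" (metabolite-effect sign)
    domain: str | None = None  # cognition only
    flags: tuple = field(default_factory=tuple)

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(np.isfinite(self.p) and self.p < alpha)


def _direction(sign: float) -> str:
    return "increase" if sign > 0 else "decrease"


def _cov_array(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    arr = np.asarray(covariates, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


# ---------------------------------------------------------------------------
# brain_group
# ---------------------------------------------------------------------------
def group_difference_po(
    y,
    group: Sequence[str],
    covariates=None,
    metabolite_id: str = "",
    groups_order: Sequence[str] = ("CN", "ASYMAD", "AD"),
    test: str = "score",
) -> EndophenotypeResult:
    """Proportional-odds test for concentration differences across groups.

    The (log) concentration is the outcome, treated as ordinal over its
    distinct observed values; group enters as a nominal factor with the first
    element of ``groups_order`` as reference. The p-value is the global test
    for the group factor: the default ``test="score"`` is the Rao score test
    at the covariate-adjusted null — the proportional-odds generalization of
    the Wilcoxon / Kruskal–Wallis rank tests, and exactly those statistics
    when no covariates are supplied. ``test="lr"`` gives the likelihood-ratio
    variant (mildly anticonservative when the distinct-value count
    approaches n). The direction is the sign of the AD-vs-reference
    coefficient from the full maximum-likelihood fit.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = [g for g in groups_order if g in set(group)]
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    cov = _cov_array(covariates)
    X_full = dummies if cov is None else np.column_stack([dummies, cov])
    full = fit_proportional_odds(y, X_full)
    df = len(levels) - 1
    if test == "score":
        _, p = score_test(y, dummies, X_adjust=cov)
    elif test == "lr":
        if cov is None:
            ll0 = null_loglik(y)
        else:
            ll0 = fit_proportional_odds(y, cov).loglik
        lr = max(2.0 * (full.loglik - ll0), 0.0)
        p = float(stats.chi2.sf(lr, df))
    else:
        raise ValueError(f"unknown test {test!r}")
    ad_idx = levels[1:].index("AD") if "AD" in levels[1:] else 0
    est = float(full.beta[ad_idx])
    se = float(full.beta_se[ad_idx])
    z = stats.norm.ppf(0.975)
    return EndophenotypeResult(
        metabolite_id, "brain_group", est, est - z * se, est + z * se,
        p, full.n, _direction(est),
    )


# ---------------------------------------------------------------------------
# cerad / braak
# ---------------------------------------------------------------------------
def adjusted_spearman(
    x,
    y,
    covariates=None,
    metabolite_id: str = "",
    category: str = "cerad",
) -> EndophenotypeResult:
    """Covariate-adjusted Spearman rank correlation (partial Spearman).

    Both variables are rank-transformed (midranks for ties), each rank vector
    is residualized on the covariates by least squares, and the estimate is
    the Pearson correlation of the residuals. Inference: t reference with
    n − 2 − q df; CI via the Fisher z transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    cov = _cov_array(covariates)
    q = 0 if cov is None else cov.shape[1]
    design = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    rho = float((ex * ey).sum() / denom) if denom > 0 else np.nan
    df = n - 2 - q
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    # Fisher z CI
    if abs(rho) < 1.0 and n - 3 - q > 0:
        zr = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3 - q)
        zc = stats.norm.ppf(0.975)
        lo, hi = np.tanh(zr - zc * se), np.tanh(zr + zc * se)
    else:
        lo = hi = rho
    return EndophenotypeResult(
        metabolite_id, category, rho, float(lo), float(hi), p, n, _direction(rho)
    )


# ---------------------------------------------------------------------------
# blsa_cox / adni_cox
# ---------------------------------------------------------------------------
def cox_conversion(
    x,
    time,
    event,
    covariates: pd.DataFrame | None = None,
    metabolite_id: str = "",
    category: str = "blsa_cox",
) -> EndophenotypeResult:
    """Cox proportional-hazards model for conversion to incident AD.

    The estimate is the hazard ratio per 1 log-unit increase in the
    (log-transformed) metabolite concentration; ties are handled by Efron's
    method; inference is Wald. A monotone likelihood (complete separation)
    yields a flagged result with missing p.
    """
    df = pd.DataFrame({"x": np.asarray(x, dtype=float),
                       "time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int)})
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], dtype=float)
    n_events = int(df["event"].sum())
    if n_events < 5:
        raise ValueError(f"need at least 5 events, got {n_events}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # default Newton stopping leaves ~1e-4 error in the coefficients;
            # tighten so estimates agree with the partial-likelihood optimum
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-9})
    except (LifelinesConvergenceError, np.linalg.LinAlgError) as err:
        return EndophenotypeResult(
            metabolite_id, category, np.nan, np.nan, np.nan, np.nan,
            len(df), "increase", flags=("separation", str(err)[:80]),
        )
    coef = float(cph.params_["x"])
    flags: tuple = ()
    if abs(coef) > 15:  # monotone likelihood drifts to huge coefficients
        flags = ("separation",)
        p = np.nan
    else:
        p = float(cph.summary.loc["x", "p"])
    hr = float(np.exp(coef))
    lo = float(np.exp(cph.confidence_intervals_.loc["x"].iloc[0]))
    hi = float(np.exp(cph.confidence_intervals_.loc["x"].iloc[1]))
    return EndophenotypeResult(
        metabolite_id, category, hr, lo, hi, p, len(df),
        "increase" if hr > 1 else "decrease", flags=flags,
    )


# ---------------------------------------------------------------------------
# blsa_cognition
# ---------------------------------------------------------------------------
def lme_trajectory(
    visits: pd.DataFrame,
    x: pd.Series,
    covariates: pd.DataFrame,
    domain_cols: Sequence[str] = DOMAINS,
    metabolite_id: str = "",
    time_col: str = "time_days",
) -> list[EndophenotypeResult]:
    """Linear mixed models for metabolite × time effects on cognitive slopes.

    One model per domain composite. Fixed effects: metabolite, age, sex, time
    and each predictor's interaction with time; random intercept and slope per
    subject (unstructured 2×2 covariance); REML estimation (the dedicated
    profiled fitter in :mod:`easead.lmm`), Wald inference. The reported
    estimate is the metabolite × time coefficient on a per-year scale — the
    change in annualized rate of cognitive change per 1 log-unit of
    concentration.

    ``visits`` is long over subjects and visits, with ``subject_id``,
    ``time_col`` (days since baseline) and one column per domain composite.
    ``x``/``covariates`` are indexed by subject_id.
    """
    xv = x.loc[visits["subject_id"]].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError("metabolite concentration is constant; interaction non-identifiable")
    t_years = visits[time_col].to_numpy(dtype=float) / 365.25
    exog = pd.DataFrame({"const": 1.0, "met": xv, "time": t_years, "met_time": xv * t_years})
    for c in covariates.columns:
        vals = covariates[c].loc[visits["subject_id"]].to_numpy(dtype=float)
        exog[c] = vals
        exog[f"{c}_time"] = vals * t_years
    groups = visits["subject_id"].to_numpy()
    mt_idx = list(exog.columns).index("met_time")
    results = []
    for dom in domain_cols:
        endog = visits[dom].to_numpy(dtype=float)
        mask = np.isfinite(endog)
        try:
            fit = fit_random_slope(
                endog[mask], exog.loc[mask].to_numpy(), groups[mask], t_years[mask])
        except np.linalg.LinAlgError as err:
            results.append(EndophenotypeResult(
                metabolite_id, "blsa_cognition", np.nan, np.nan, np.nan,
                np.nan, int(mask.sum()), "decrease", domain=dom,
                flags=("nonconvergence", str(err)[:80]),
            ))
            continue
        if not fit.converged:
            results.append(EndophenotypeResult(
                metabolite_id, "blsa_cognition", np.nan, np.nan, np.nan,
                np.nan, int(mask.sum()), "decrease", domain=dom,
                flags=("nonconvergence",),
            ))
            continue
        est = float(fit.beta[mt_idx])
        se = float(fit.bse[mt_idx])
        z = stats.norm.ppf(0.975)
        p = float(2.0 * stats.norm.sf(abs(est / se))) if se > 0 else np.nan
        results.append(EndophenotypeResult(
            metabolite_id, "blsa_cognition", est, est - z * se, est + z * se,
            p, int(mask.sum()), _direction(est), domain=dom,
        ))
    return results


# ---------------------------------------------------------------------------
# spare_ad / csf_*
# ---------------------------------------------------------------------------
def linear_endophenotype(
    x,
    y,
    covariates=None,
    metabolite_id: str = "",
    category: str = "spare_ad",
) -> EndophenotypeResult:
    """OLS of a cross-sectional endophenotype on ln metabolite concentration.

    CSF outcomes are expected natural-log transformed upstream. The estimate
    is the metabolite slope with Wald CI/p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cov = _cov_array(covariates)
    design = np.column_stack([np.ones(n), x] if cov is None else [np.ones(n), x, cov])
    if np.linalg.cond(design) > 1e10:
        raise ValueError("collinear design (condition number over cap)")
    fit = sm.OLS(y, design).fit()
    est = float(fit.params[1])
    lo, hi = (float(v) for v in fit.conf_int()[1])
    return EndophenotypeResult(
        metabolite_id, category, est, lo, hi, float(fit.pvalues[1]),
        n, _direction(est),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------
def run_battery(
    panel: Sequence[str],
    brain=None,
    preclinical=None,
    prodromal=None,
    alpha: float = 0.05,
    region: str = "ITG",
) -> list[EndophenotypeResult]:
    """Fit every available category model for every panel metabolite.

    Cohort arguments are preprocessed :class:`easead.synthetic.SyntheticCohort`
    objects (or anything with the same attributes); concentrations must
    already be natural-log transformed. A missing cohort skips its categories.
    Cognitive-trajectory models are fit among converters only, mirroring the
    preclinical design (trajectories prior to symptom onset in individuals
    who later convert).
    """
    if not panel:
        raise ValueError("panel is empty")
    results: list[EndophenotypeResult] = []
    for met in panel:
        if brain is not None:
            mat = brain.concentrations[region]
            yv = mat.values[met]
            meta = brain.metadata.set_index("sample_id").loc[yv.index]
            cov = np.column_stack([meta["age"], meta["sex"]])
            results.append(group_difference_po(yv, meta["group"], cov, metabolite_id=met))
            npth = brain.neuropath.set_index("subject_id").loc[meta["subject_id"]]
            for cat, col in (("cerad", "cerad"), ("braak", "braak")):
                results.append(adjusted_spearman(
                    yv, npth[col], cov, metabolite_id=met, category=cat))
        if preclinical is not None:
            mat = preclinical.concentrations
            xv = mat.values[met]
            meta = preclinical.metadata.set_index("sample_id").loc[xv.index]
            surv = preclinical.survival.set_index("subject_id").loc[meta["subject_id"]]
            cov = pd.DataFrame({"age": meta["age"].to_numpy(),
                                "sex": meta["sex"].to_numpy(dtype=float)})
            results.append(cox_conversion(
                xv, surv["time"], surv["event"], cov, metabolite_id=met))
            conv_subj = meta.loc[meta["group"] == "converter", "subject_id"]
            vis = preclinical.visits[preclinical.visits["subject_id"].isin(conv_subj)]
            if len(vis):
                x_subj = pd.Series(xv.to_numpy(), index=meta["subject_id"].to_numpy())
                cov_subj = pd.DataFrame(
                    {"age": meta["age"].to_numpy(), "sex": meta["sex"].to_numpy(dtype=float)},
                    index=meta["subject_id"].to_numpy(),
                )
                results.extend(lme_trajectory(vis, x_subj, cov_subj, metabolite_id=met))
        if prodromal is not None:
            mat = prodromal.concentrations
            xv = mat.values[met]
            meta = prodromal.metadata.set_index("sample_id").loc[xv.index]
            xs = prodromal.xsect.set_index("subject_id").loc[meta["subject_id"]]
            cov = np.column_stack([meta["age"], meta["sex"]])
            for cat, col, logged in (
                ("spare_ad", "spare_ad", False),
                ("csf_abeta", "abeta", True),
                ("csf_ttau", "ttau", True),
                ("csf_ptau", "ptau", True),
            ):
                yv = np.log(xs[col].to_numpy(dtype=float)) if logged else xs[col].to_numpy(dtype=float)
                results.append(linear_endophenotype(
                    xv, yv, cov, metabolite_id=met, category=cat))
            mci = meta["group"] == "MCI"
            surv = prodromal.survival.set_index("subject_id").loc[meta.loc[mci, "subject_id"]]
            cov_mci = pd.DataFrame({"age": meta.loc[mci, "age"].to_numpy(),
                                    "sex": meta.loc[mci, "sex"].to_numpy(dtype=float)})
            results.append(cox_conversion(
                xv[mci.to_numpy()], surv["time"], surv["event"], cov_mci,
                metabolite_id=met, category="adni_cox"))
    return results


def results_to_frame(results: Sequence[EndophenotypeResult], alpha: float = 0.05) -> pd.DataFrame:
    """Uniform long-format results table (one row per fitted model)."""
    rows = [{
        "metabolite": r.metabolite_id, "category": r.category,
        "domain": r.domain or "", "estimate": r.estimate,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p, "n": r.n,
        "direction": r.direction, "significant": r.significant(alpha),
    } for r in results]
    return pd.DataFrame(rows)


def frame_to_results(frame: pd.DataFrame) -> list[EndophenotypeResult]:
    """Inverse of :func:`results_to_frame` (the ``significant`` column is
    derived, not stored)."""
    out = []
    for row in frame.itertuples(index=False):
        domain = getattr(row, "domain", "") or None
        if isinstance(domain, float) and np.isnan(domain):
            domain = None
        out.append(EndophenotypeResult(
            row.metabolite, row.category, row.estimate, row.ci_low,
            row.ci_high, row.p, int(row.n), row.direction, domain=domain))
    return out
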