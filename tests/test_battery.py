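"""The endophenotype association models, each checked against an
independent oracle, plus the battery orchestration contract."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from easead.battery import (
    adjusted_spearman,
    cox_conversion,
    group_difference_po,
    linear_endophenotype,
    lme_trajectory,
    run_battery,
)
from easead.composites import build_composites, truncate_post_onset
from easead.pipeline import _preprocess_brain, _preprocess_serum
from easead.preprocess import DEFAULT_IMPUTE_MODE
from easead.synthetic import (
    generate_brain_cohort,
    generate_preclinical_cohort,
    generate_prodromal_cohort,
)
from conftest import small_config


class TestGroupDifferencePO:
    def test_two_group_score_test_is_the_wilcoxon_rank_sum(self):
        """The proportional-odds score test *is* the two-sample rank test:
        identical to the asymptotic Wilcoxon, within 0.02 of the exact one."""
        rng = np.random.default_rng(8)
        for n_per in (12, 20):
            y = rng.normal(size=2 * n_per)
            g = np.array(["AD"] * n_per + ["CN"] * n_per)
            res = group_difference_po(y, g, groups_order=("CN", "AD"), test="score")
            asym = stats.mannwhitneyu(
                y[g == "AD"], y[g == "CN"],
                method="asymptotic", use_continuity=False)
            assert res.p == pytest.approx(asym.pvalue, abs=1e-10)
            exact = stats.mannwhitneyu(y[g == "AD"], y[g == "CN"], method="exact")
            assert abs(res.p - exact.pvalue) < 0.02 + (0.01 if n_per < 15 else 0)

    def test_three_group_score_test_close_to_kruskal_wallis(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            y = rng.normal(size=36)
            g = np.repeat(["CN", "ASYMAD", "AD"], 12)
            res = group_difference_po(y, g, test="score")
            kw = stats.kruskal(y[g == "CN"], y[g == "ASYMAD"], y[g == "AD"])
            assert abs(res.p - kw.pvalue) < 0.02

    def test_matches_statsmodels_ordered_model(self):
        """Dual route: the direct likelihood fit equals the generic fitter."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        rng = np.random.default_rng(1)
        y = rng.normal(size=30) + np.repeat([0.0, 0.6, 1.2], 10)
        g = np.repeat(["CN", "ASYMAD", "AD"], 10)
        cov = rng.normal(size=(30, 1))
        res = group_difference_po(y, g, cov)
        codes = pd.Series(y).rank(method="dense").astype(int) - 1
        X = pd.DataFrame({
            "asymad": (g == "ASYMAD").astype(float),
            "ad": (g == "AD").astype(float),
            "c0": (cov - cov.mean(axis=0)).ravel(),
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = OrderedModel(codes, X, distr="logit").fit(
                method="bfgs", disp=False, maxiter=500)
        assert res.estimate == pytest.approx(float(sm_fit.params["ad"]), abs=1e-3)

    def test_ordered_groups_detected(self):
        """AD strictly above CN with ASYMAD intermediate → positive AD effect."""
        rng = np.random.default_rng(5)
        y = np.concatenate([
            rng.uniform(0, 1, 15),        # CN
            rng.uniform(0.8, 1.8, 15),    # ASYMAD
            rng.uniform(1.6, 2.6, 15),    # AD
        ])
        g = np.repeat(["CN", "ASYMAD", "AD"], 15)
        res = group_difference_po(y, g)
        assert res.estimate > 0
        assert res.p < 0.01
        assert res.direction == "increase"

    def test_null_three_groups_uniform_p(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(120):
            y = rng.normal(size=45)
            g = np.repeat(["CN", "ASYMAD", "AD"], 15)
            pvals.append(group_difference_po(y, g).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            group_difference_po(np.arange(6.0), np.array(["AD"] * 6))


class TestAdjustedSpearman:
    def test_classical_value_with_constant_covariates(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 2, 3, 5, 4])
        res = adjusted_spearman(x, y, np.ones((5, 1)))
        assert res.estimate == pytest.approx(0.9, abs=1e-12)

    def test_monotone_function_gives_one(self):
        x = np.array([0.3, 1.1, 2.0, 3.5, 4.0, 7.7])
        res = adjusted_spearman(x, np.exp(x), np.full((6, 1), 2.0))
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_equals_scipy_spearman_without_covariates(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.integers(0, 4, 40).astype(float)
        res = adjusted_spearman(x, y)
        rho = stats.spearmanr(x, y).statistic
        assert res.estimate == pytest.approx(rho, abs=1e-12)

    def test_agrees_with_pingouin_partial_spearman(self):
        """Independent cross-check of the residualized-rank construction."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n = 44
        df = pd.DataFrame({
            "x": rng.normal(size=n),
            "y": rng.integers(0, 7, n).astype(float),
            "age": rng.normal(80, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
        })
        # pingouin rank-transforms the covariates too, so feed it the same
        # construction by passing ranked covariates to our estimator
        ranked_cov = df[["age", "sex"]].rank()
        res = adjusted_spearman(df["x"], df["y"], ranked_cov)
        pg = pingouin.partial_corr(
            df, x="x", y="y", covar=["age", "sex"], method="spearman")
        assert res.estimate == pytest.approx(float(pg["r"].iloc[0]), abs=1e-10)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adjusted_spearman(np.arange(8.0), np.ones(8))


def _grid_cox_loglik(beta, x, time, event):
    """Hand-written Cox partial log-likelihood (no ties)."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    ll = 0.0
    for i in range(len(x)):
        if event[i]:
            risk = x[i] * beta
            denom = np.log(np.sum(np.exp(x[time >= time[i]] * beta)))
            ll += risk - denom
    return ll


class TestCoxConversion:
    def test_identical_event_multisets_give_unit_hazard_ratio(self):
        x = np.array([1.0] * 6 + [0.0] * 6)
        time = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 2)
        event = np.ones(12, dtype=int)
        res = cox_conversion(x, time, event)
        assert res.estimate == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_partial_likelihood(self):
        """6-subject, no ties: estimate equals the brute-force maximizer."""
        x = np.array([0.2, -1.1, 0.8, 1.6, -0.4, 0.1])
        time = np.array([2.0, 5.0, 1.0, 3.0, 4.0, 6.0])
        event = np.array([1, 1, 1, 1, 1, 0])
        res = cox_conversion(x, time, event)
        grid = np.linspace(-3, 3, 60001)
        lls = [_grid_cox_loglik(b, x, time, event) for b in grid]
        beta_hat = grid[int(np.argmax(lls))]
        assert np.log(res.estimate) == pytest.approx(beta_hat, abs=1e-4)

    def test_separation_flagged(self):
        x = np.array([1.0] * 5 + [0.0] * 5)
        time = np.r_[np.arange(1.0, 6.0), np.arange(10.0, 15.0)]
        event = np.ones(10, dtype=int)
        res = cox_conversion(x, time, event)
        assert "separation" in res.flags and np.isnan(res.p)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_conversion(np.arange(10.0), np.arange(1.0, 11.0),
                           np.r_[np.ones(3), np.zeros(7)].astype(int))


class TestLmeTrajectory:
    def _visits(self, n_subj, slopes, intercepts=None, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subj):
            for t in (0.0, 2.0, 4.0, 6.0):
                z = (intercepts[i] if intercepts is not None else 0.0) \
                    + slopes[i] * t + (rng.normal(0, noise) if noise else 0.0)
                rows.append({"subject_id": f"s{i}", "time_days": t * 365.25,
                             "memory": z})
        return pd.DataFrame(rows)

    def test_noiseless_interaction_recovered_exactly(self):
        n = 30
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        age = pd.Series(rng.normal(75, 5, n), index=x.index)
        sex = pd.Series(rng.integers(0, 2, n).astype(float), index=x.index)
        slopes = -0.05 + -0.10 * x.to_numpy() + 0.002 * age.to_numpy()
        visits = self._visits(n, slopes)
        res = lme_trajectory(
            visits, x, pd.DataFrame({"age": age, "sex": sex}),
            domain_cols=("memory",))[0]
        assert res.estimate == pytest.approx(-0.10, abs=1e-6)

    def test_constant_metabolite_rejected(self):
        x = pd.Series(1.0, index=[f"s{i}" for i in range(10)])
        visits = self._visits(10, np.zeros(10))
        with pytest.raises(ValueError, match="constant"):
            lme_trajectory(visits, x, pd.DataFrame({"age": x}), ("memory",))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reml_fit_matches_statsmodels(self, seed):
        """Dual route: the profiled REML fitter agrees with the generic
        mixed-model machinery on estimates, SEs and restricted likelihood."""
        import statsmodels.api as sm
        from easead.lmm import fit_random_slope

        rng = np.random.default_rng(seed)
        n_subj, n_vis = 40, 4
        subj = np.repeat(np.arange(n_subj), n_vis)
        t = np.tile(np.arange(n_vis) * 2.0, n_subj)
        xmet = rng.normal(size=n_subj)[subj]
        b0 = rng.normal(0, 0.8, n_subj)[subj]
        b1 = rng.normal(0, 0.06, n_subj)[subj]
        y = 0.2 + b0 + (-0.05 - 0.08 * xmet + b1) * t + rng.normal(0, 0.3, len(t))
        ex = pd.DataFrame({"const": 1.0, "met": xmet, "time": t, "mt": xmet * t})
        mine = fit_random_slope(y, ex.to_numpy(), subj, t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(y, ex, groups=subj,
                             exog_re=ex[["const", "time"]]).fit(
                reml=True, method="powell")
        assert mine.beta[3] == pytest.approx(float(ref.params["mt"]), abs=1e-5)
        assert mine.bse[3] == pytest.approx(float(ref.bse["mt"]), rel=1e-3)
        assert mine.loglik == pytest.approx(float(ref.llf), abs=1e-3)


class TestLinearEndophenotype:
    def test_exact_linear_construction(self):
        rng = np.random.default_rng(0)
        n = 40
        x = rng.normal(size=n)
        age = rng.normal(75, 6, n)
        y = 0.5 * x + 0.1 * age
        res = linear_endophenotype(x, y, age)
        assert res.estimate == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations_on_five_points(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 0.5, 2.0, 1.5, 3.0])
        res = linear_endophenotype(x, y)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.estimate == pytest.approx(beta[1], abs=1e-12)

    def test_collinear_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            linear_endophenotype(x, x, 2.0 * x + 1.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        hits, n_rep = 0, 400
        for _ in range(n_rep):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            hits += linear_endophenotype(x, y).p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07


def _processed_cohorts(seed=0, **overrides):
    config = small_config(seed=seed, **overrides)
    brain = _preprocess_brain(generate_brain_cohort(config),
                              DEFAULT_IMPUTE_MODE["brain"])
    precl = _preprocess_serum(generate_preclinical_cohort(config),
                              DEFAULT_IMPUTE_MODE["preclinical"], 5.0, True)
    prodr = _preprocess_serum(generate_prodromal_cohort(config),
                              DEFAULT_IMPUTE_MODE["prodromal"], 5.0, False)
    return brain, precl, prodr


class TestRunBattery:
    def test_single_metabolite_yields_nine_plus_domains(self):
        brain, precl, prodr = _processed_cohorts()
        results = run_battery(["SM001"], brain, precl, prodr)
        assert len(results) == 9 + 5
        cats = {r.category for r in results}
        assert len(cats) == 10

    def test_missing_cohort_skips_its_categories(self):
        brain, precl, _ = _processed_cohorts()
        results = run_battery(["SM001"], brain, precl, None)
        cats = {r.category for r in results}
        assert "adni_cox" not in cats and "spare_ad" not in cats
        assert {"brain_group", "cerad", "braak", "blsa_cox",
                "blsa_cognition"} <= cats

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            run_battery([], None, None, None)

    def test_sign_flip_reverses_directions_and_preserves_p(self):
        """Negating one metabolite's log-concentrations flips every direction
        but leaves every p-value unchanged."""
        brain, precl, prodr = _processed_cohorts(seed=6)
        met = "SM001"
        base = run_battery([met], brain, precl, prodr)
        for cohort in (brain, precl, prodr):
            conc = cohort.concentrations
            if isinstance(conc, dict):
                for mat in conc.values():
                    mat.values[met] = -mat.values[met]
            else:
                conc.values[met] = -conc.values[met]
        flipped = run_battery([met], brain, precl, prodr)
        for a, b in zip(base, flipped):
            assert a.category == b.category and a.domain == b.domain
            if np.isnan(a.p) or np.isnan(b.p):
                # a flagged fit (separation, nonconvergence) on tiny data
                # must be flagged identically on the sign-flipped data;
                # its p is deliberately missing on both sides
                assert np.isnan(a.p) and np.isnan(b.p)
                assert a.flags[:1] == b.flags[:1]
                continue
            if a.category == "brain_group":
                # the metabolite is the *outcome* here; reversing its order
                # flips the group coefficient and preserves the LR p
                assert a.p == pytest.approx(b.p, abs=1e-5)
                assert a.direction != b.direction
                continue
            assert a.direction != b.direction
            assert a.p == pytest.approx(b.p, rel=1e-5, abs=1e-7)
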