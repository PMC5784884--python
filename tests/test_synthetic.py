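"""The synthetic cohort generators: determinism, null calibration and
recoverability of planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from easead.synthetic import (
    SyntheticConfig,
    generate_brain_cohort,
    generate_preclinical_cohort,
    generate_prodromal_cohort,
)
from conftest import small_config


def _cohort_signature(cohort):
    """Stable byte-level digest of every frame in a cohort."""
    parts = []
    conc = cohort.concentrations
    mats = conc.values() if isinstance(conc, dict) else [conc]
    for m in mats:
        parts.append(m.values.to_csv())
        parts.append(m.below_lod.to_csv())
        parts.append(m.lod.to_csv())
    for name in ("metadata", "neuropath", "survival", "visits", "xsect"):
        f = getattr(cohort, name)
        if f is not None:
            parts.append(f.to_csv())
    return "".join(parts)


@pytest.mark.parametrize("generator", [
    generate_brain_cohort, generate_preclinical_cohort, generate_prodromal_cohort,
])
def test_same_seed_byte_identical(generator):
    a = generator(small_config(seed=11))
    b = generator(small_config(seed=11))
    assert _cohort_signature(a) == _cohort_signature(b)
    c = generator(small_config(seed=12))
    assert _cohort_signature(a) != _cohort_signature(c)


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="sum"):
        small_config(n_metabolites=10)
    with pytest.raises(ValueError, match="lod_quantile"):
        small_config(lod_quantile=1.0)
    with pytest.raises(ValueError, match="positive"):
        small_config(group_sizes={"AD": 0, "CN": 5, "ASYMAD": 5})


class TestBrainCohort:
    def test_structure(self, null_config):
        cohort = generate_brain_cohort(null_config)
        assert set(cohort.concentrations) == {"MFG", "ITG", "CBL"}
        for mat in cohort.concentrations.values():
            assert mat.values.shape == (44, 12)
            assert (mat.values.to_numpy() > 0).all()
        # censoring respects the per-metabolite LOD
        mat = cohort.concentrations["ITG"]
        flagged = mat.below_lod.to_numpy()
        assert (mat.values.to_numpy()[flagged] < mat.lod.to_numpy()[
            np.where(flagged)[1]]).all()

    def test_neuropath_monotone_in_group(self, null_config):
        scores = pd.concat([
            generate_brain_cohort(small_config(seed=s)).neuropath
            for s in range(10)
        ])
        means = scores.groupby("group")[["cerad", "braak"]].mean()
        assert means.loc["CN", "cerad"] < means.loc["ASYMAD", "cerad"]
        assert means.loc["ASYMAD", "cerad"] <= means.loc["AD", "cerad"]
        assert means.loc["CN", "braak"] < means.loc["AD", "braak"]

    def test_null_false_positive_rate_in_binomial_band(self):
        """With no planted shifts, AD-vs-CN t-tests reject ~5% of metabolites."""
        config = small_config(
            seed=42, n_metabolites=187,
            family_composition={
                "acylcarnitine": 40, "amino acid": 21, "biogenic amine": 21,
                "glycerophospholipid": 89, "sphingolipid": 15, "hexose": 1},
            group_sizes={"AD": 200, "CN": 200},
        )
        cohort = generate_brain_cohort(config)
        meta = cohort.metadata
        mat = cohort.concentrations["ITG"].values
        ad = meta[(meta["region"] == "ITG") & (meta["group"] == "AD")]["sample_id"]
        cn = meta[(meta["region"] == "ITG") & (meta["group"] == "CN")]["sample_id"]
        logv = np.log(mat)
        _, p = stats.ttest_ind(logv.loc[ad], logv.loc[cn])
        hits = int((p < 0.05).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 187, 0.05)
        assert lo <= hits <= hi

    def test_planted_shift_confined_to_region(self):
        """A shift planted in one region is detectable there and only there."""
        p_target, p_other = [], []
        for seed in range(25):
            config = small_config(
                seed=seed, planted_brain_effects={"SM001": ("ITG", 1.5, 0.5)})
            cohort = generate_brain_cohort(config)
            meta = cohort.metadata
            for region in ("MFG", "ITG", "CBL"):
                mat = cohort.concentrations[region].values
                sel = meta[meta["region"] == region]
                ad = np.log(mat.loc[sel[sel["group"] == "AD"]["sample_id"], "SM001"])
                cn = np.log(mat.loc[sel[sel["group"] == "CN"]["sample_id"], "SM001"])
                _, p = stats.ttest_ind(ad, cn, equal_var=False)
                (p_target if region == "ITG" else p_other).append(p)
        assert np.mean(np.array(p_target) < 0.01) >= 0.8
        assert stats.kstest(p_other, "uniform").pvalue > 0.01

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            generate_brain_cohort(small_config(
                planted_brain_effects={"SM001": ("HIP", 1.0, 0.5)}))


class TestPreclinicalCohort:
    def test_structure(self, null_config):
        cohort = generate_preclinical_cohort(null_config)
        n = 80
        assert cohort.concentrations.values.shape == (n, 12)
        assert len(cohort.survival) == n
        assert (cohort.survival["time"] <= null_config.censor_time + 1e-12).all()
        conv = cohort.metadata["group"] == "converter"
        assert (cohort.survival["event"].to_numpy() == conv.to_numpy()).all()
        assert cohort.metadata.loc[conv, "onset_age"].notna().all()
        assert cohort.metadata.loc[~conv, "onset_age"].isna().all()
        # biennial visits from baseline to the censoring horizon
        times = np.sort(cohort.visits["time_days"].unique())
        np.testing.assert_allclose(times, np.arange(5) * 2 * 365.25)

    def test_metso_contamination_rate_matches_study_design(self):
        """Expected count above 5 μM at the study's per-group rates ≈ 43/250."""
        counts = []
        for seed in range(20):
            config = small_config(
                seed=seed,
                preclinical_group_sizes={"converter": 126, "non-converter": 124})
            cohort = generate_preclinical_cohort(config)
            counts.append((cohort.metadata["metso"] > 5.0).sum())
        # per-group fractions are tied to realized converter status, so the
        # expectation is ~43 with binomial noise
        assert 35 <= np.mean(counts) <= 51

    def test_storage_time_imbalance(self, null_config):
        cohort = generate_preclinical_cohort(null_config)
        meta = cohort.metadata
        gap = (meta[meta["group"] == "converter"]["storage_time"].mean()
               - meta[meta["group"] == "non-converter"]["storage_time"].mean())
        assert 2.0 < gap < 7.0

    def test_null_hazard_independent_of_metabolites(self):
        """Score-test p-values are uniform across seeds under the null."""
        from lifelines.statistics import proportional_hazard_test  # noqa: F401
        from lifelines import CoxPHFitter
        pvals = []
        for seed in range(40):
            cohort = generate_preclinical_cohort(small_config(seed=seed))
            df = pd.DataFrame({
                "x": np.log(cohort.concentrations.values["SM001"]).to_numpy(),
                "time": cohort.survival["time"].to_numpy(),
                "event": cohort.survival["event"].to_numpy(),
            })
            cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
            pvals.append(float(cph.summary.loc["x", "p"]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_censor_time_validated(self):
        with pytest.raises(ValueError, match="censor_time"):
            generate_preclinical_cohort(small_config(censor_time=0.0))


class TestProdromalCohort:
    def test_structure(self, null_config):
        cohort = generate_prodromal_cohort(null_config)
        assert cohort.concentrations.values.shape == (90, 12)
        assert len(cohort.survival) == 40  # MCI only
        assert set(cohort.xsect.columns) == {
            "subject_id", "spare_ad", "abeta", "ttau", "ptau"}
        assert (cohort.xsect[["abeta", "ttau", "ptau"]].to_numpy() > 0).all()

    def test_group_polarity_of_endophenotypes(self, null_config):
        cohort = generate_prodromal_cohort(null_config)
        merged = cohort.xsect.merge(
            cohort.metadata[["subject_id", "group"]], on="subject_id")
        means = merged.groupby("group").mean(numeric_only=True)
        assert means.loc["AD", "spare_ad"] > means.loc["CN", "spare_ad"]
        assert means.loc["AD", "abeta"] < means.loc["CN", "abeta"]
        assert means.loc["AD", "ttau"] > means.loc["CN", "ttau"]

    def test_planted_slope_recovered_by_ols(self):
        """OLS on generated data recovers a planted atrophy-index slope."""
        import statsmodels.api as sm
        estimates = []
        for seed in range(25):
            config = small_config(
                seed=seed,
                prodromal_group_sizes={"CN": 120, "MCI": 120, "AD": 110},
                planted_xsect_beta={"SM001": ("spare_ad", 0.5)})
            cohort = generate_prodromal_cohort(config)
            x = np.log(cohort.concentrations.values["SM001"]).to_numpy()
            meta = cohort.metadata
            design = np.column_stack([
                np.ones(len(x)), x, meta["age"], meta["sex"]])
            fit = sm.OLS(cohort.xsect["spare_ad"].to_numpy(), design).fit()
            estimates.append(fit.params[1])
        assert 0.42 <= np.mean(estimates) <= 0.58

    def test_null_slopes_centered_on_zero(self):
        import statsmodels.api as sm
        estimates = []
        for seed in range(25):
            cohort = generate_prodromal_cohort(small_config(seed=seed))
            x = np.log(cohort.concentrations.values["PC001"]).to_numpy()
            fit = sm.OLS(cohort.xsect["spare_ad"].to_numpy(),
                         np.column_stack([np.ones(len(x)), x])).fit()
            estimates.append(fit.params[1])
        assert abs(np.mean(estimates)) < 0.1

    def test_unknown_endophenotype_rejected(self):
        with pytest.raises(ValueError, match="endophenotype"):
            generate_prodromal_cohort(small_config(
                planted_xsect_beta={"SM001": ("amyloid_pet", 0.5)}))


def test_doubling_planted_hr_does_not_shrink_estimates():
    """Monotone plantedness: stronger planted hazard → larger median effect."""
    from lifelines import CoxPHFitter

    def median_loghr(loghr):
        out = []
        for seed in range(12):
            config = small_config(
                seed=seed, planted_log_hr={"SM001": loghr},
                preclinical_group_sizes={"converter": 80, "non-converter": 80})
            cohort = generate_preclinical_cohort(config)
            df = pd.DataFrame({
                "x": np.log(cohort.concentrations.values["SM001"]).to_numpy(),
                "time": cohort.survival["time"].to_numpy(),
                "event": cohort.survival["event"].to_numpy()})
            cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
            out.append(abs(float(cph.params_["x"])))
        return np.median(out)

    assert median_loghr(np.log(2)) >= median_loghr(np.log(1.2))
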