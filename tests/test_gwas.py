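"""Association scans and LD pruning against closed forms and statsmodels."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from particle_mr.gwas import associate, filter_and_prune
from conftest import make_tiny_cohort


def test_single_snp_no_covariates_equals_simple_regression_slope():
    dosage = [0, 0, 1, 1, 1, 2, 2, 2]
    ldl = [3.0, 3.2, 3.4, 3.5, 3.3, 3.9, 4.1, 3.8]
    cohort = make_tiny_cohort({"rs1": dosage}, phenotypes={"ldl_c": ldl})
    out = associate(cohort, "ldl_c", covariates=())
    x, y = np.asarray(dosage, float), np.asarray(ldl, float)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    assert out.loc[0, "beta"] == pytest.approx(slope, abs=1e-12)


def test_linear_scan_matches_statsmodels_ols(small_cohort):
    snps = list(small_cohort.genotypes.columns[:6])
    out = associate(small_cohort, "ldl_c", snp_ids=snps).set_index("snp_id")
    rows = ((small_cohort.phenotypes["on_lipid_lowering"] == 0)
            & small_cohort.phenotypes["ldl_c"].notna())
    covs = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
    y = small_cohort.phenotypes.loc[rows, "ldl_c"]
    for s in snps:
        X = sm.add_constant(
            pd.concat([small_cohort.genotypes.loc[rows, s],
                       small_cohort.phenotypes.loc[rows, covs]], axis=1)
        )
        fit = sm.OLS(y, X).fit()
        assert out.at[s, "beta"] == pytest.approx(fit.params[s], rel=1e-9)
        assert out.at[s, "se"] == pytest.approx(fit.bse[s], rel=1e-9)
        assert out.at[s, "pvalue"] == pytest.approx(fit.pvalues[s], rel=1e-6, abs=1e-300)


def test_logistic_scan_matches_statsmodels_logit(small_cohort):
    snps = list(small_cohort.genotypes.columns[:4])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = associate(small_cohort, "chd", snp_ids=snps,
                        subject_filter="all").set_index("snp_id")
    covs = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
    y = ((small_cohort.outcomes["prevalent_chd"] == 1)
         | (small_cohort.outcomes["incident_chd"] == 1)).astype(float)
    for s in snps:
        X = sm.add_constant(
            pd.concat([small_cohort.genotypes[s],
                       small_cohort.phenotypes[covs]], axis=1)
        )
        fit = sm.Logit(y, X).fit(disp=0)
        assert out.at[s, "beta"] == pytest.approx(fit.params[s], rel=1e-6)
        assert out.at[s, "se"] == pytest.approx(fit.bse[s], rel=1e-5)


def test_betas_invariant_to_affine_covariate_rescaling(small_cohort):
    snps = list(small_cohort.genotypes.columns[:5])
    base = associate(small_cohort, "apob_molar", snp_ids=snps)
    rescaled = small_cohort
    ph = rescaled.phenotypes.copy()
    ph["age"] = 3.0 * ph["age"] + 5.0
    import dataclasses

    cohort2 = dataclasses.replace(rescaled, phenotypes=ph)
    cohort2.latents = rescaled.latents
    out = associate(cohort2, "apob_molar", snp_ids=snps)
    np.testing.assert_allclose(out["beta"], base["beta"], rtol=1e-8)
    np.testing.assert_allclose(out["se"], base["se"], rtol=1e-8)


def test_constant_dosage_skipped_with_warning():
    cohort = make_tiny_cohort(
        {"rs1": [0, 0, 0, 0, 0, 0], "rs2": [0, 1, 2, 0, 1, 2]},
        phenotypes={"ldl_c": [3.1, 3.0, 3.6, 3.2, 3.4, 3.7]},
    )
    with pytest.warns(UserWarning, match="constant"):
        out = associate(cohort, "ldl_c", covariates=())
    assert list(out["snp_id"]) == ["rs2"]


def test_null_snps_have_calibrated_betas(small_cohort, small_associations):
    null_ids = small_cohort.snps.index[small_cohort.snps["locus"] == "NULL"]
    out = small_associations["apob_molar"].set_index("snp_id").loc[null_ids]
    within = (out["beta"].abs() < 3.0 * out["se"]).mean()
    assert within >= 0.9  # ~99.7% expected; binomial slack at 20 SNPs


class TestFilterAndPrune:
    @staticmethod
    def _assoc(pvals):
        return pd.DataFrame({"snp_id": list(pvals), "pvalue": list(pvals.values())})

    def test_perfectly_correlated_snps_collapse_to_best(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.3, 300).astype(float)
        dosages = pd.DataFrame({"a": x, "b": x, "c": x})
        assoc = self._assoc({"a": 1e-10, "b": 1e-12, "c": 1e-9})
        assert filter_and_prune(assoc, dosages) == ["b"]

    def test_independent_snps_both_retained(self):
        rng = np.random.default_rng(1)
        dosages = pd.DataFrame(
            {"a": rng.binomial(2, 0.3, 500).astype(float),
             "b": rng.binomial(2, 0.4, 500).astype(float)}
        )
        assoc = self._assoc({"a": 1e-10, "b": 1e-9})
        assert set(filter_and_prune(assoc, dosages)) == {"a", "b"}

    def test_non_significant_and_rare_snps_filtered(self):
        rng = np.random.default_rng(2)
        dosages = pd.DataFrame(
            {"sig": rng.binomial(2, 0.3, 2000).astype(float),
             "weak": rng.binomial(2, 0.3, 2000).astype(float),
             "rare": rng.binomial(2, 0.004, 2000).astype(float)}
        )
        assoc = self._assoc({"sig": 1e-9, "weak": 1e-4, "rare": 1e-20})
        assert filter_and_prune(assoc, dosages) == ["sig"]

    def test_empty_survivor_set_returns_empty_list(self):
        dosages = pd.DataFrame({"a": np.array([0.0, 1.0, 2.0, 1.0])})
        assert filter_and_prune(self._assoc({"a": 0.5}), dosages) == []

    @staticmethod
    def _oracle(assoc, dosages, p_thr, maf_thr, r2_thr):
        """Independent re-statement: ordered greedy over the r^2 graph."""
        freq = dosages.mean() / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        surv = assoc[(assoc["pvalue"] < p_thr)
                     & (assoc["snp_id"].map(maf) > maf_thr)]
        order = surv.sort_values(["pvalue", "snp_id"])["snp_id"].tolist()
        corr = dosages.corr() ** 2
        kept = []
        for s in order:
            if all(corr.loc[s, k] < r2_thr for k in kept):
                kept.append(s)
        return kept

    def test_five_snp_fixture_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.3, 400).astype(float)
        other = rng.binomial(2, 0.4, 400).astype(float)
        noise = lambda: rng.normal(0, 1, 400)
        dosages = pd.DataFrame(
            {
                "s1": base,
                "s2": np.clip(np.round(base + 0.3 * noise()), 0, 2),
                "s3": other,
                "s4": np.clip(np.round(other + 0.6 * noise()), 0, 2),
                "s5": rng.binomial(2, 0.2, 400).astype(float),
            }
        )
        assoc = self._assoc({"s1": 1e-15, "s2": 1e-11, "s3": 1e-9,
                             "s4": 1e-13, "s5": 1e-10})
        got = filter_and_prune(assoc, dosages, r2_threshold=0.3)
        expected = self._oracle(assoc, dosages, 5e-8, 0.01, 0.3)
        assert got == expected
        assert "s1" in got  # minimum-p SNP always survives

    def test_stricter_r2_yields_subset_no_larger(self, small_cohort,
                                                 small_associations):
        assoc = small_associations["lpa_mass"]
        loose = filter_and_prune(assoc, small_cohort.genotypes, r2_threshold=0.1)
        strict = filter_and_prune(assoc, small_cohort.genotypes, r2_threshold=0.01)
        assert len(strict) <= len(loose)
        assert set(strict) <= set(assoc["snp_id"])

    def test_pruned_set_is_independent_in_r2_graph(self, small_cohort,
                                                   small_associations):
        assoc = small_associations["lpa_mass"]
        kept = filter_and_prune(assoc, small_cohort.genotypes)
        assert kept, "expected genome-wide hits in the simulated locus"
        corr = small_cohort.genotypes[kept].corr().to_numpy() ** 2
        off_diag = corr[~np.eye(len(kept), dtype=bool)]
        assert (off_diag < 0.1).all()
        best = assoc.dropna().sort_values(["pvalue", "snp_id"]).iloc[0]["snp_id"]
        assert best in kept
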