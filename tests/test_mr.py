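"""Mendelian-randomisation estimators against WLS oracles and closed forms."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from particle_mr.clusters import ClusterError, SnpCluster
from particle_mr.mr import (EggerEstimator, IvwEstimator,
                            WeightedMedianEstimator, egger, ivw,
                            run_mr_for_cluster, weighted_median)


def _random_inputs(seed, k=12):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(2, 40, k)
    se = rng.uniform(0.01, 0.06, k)
    by = 0.004 * bx + rng.normal(0, se)
    return bx, by, se


class TestIvw:
    def test_single_snp_table_row(self):
        est = ivw([50.0], [0.25], [0.1])
        assert est.theta == pytest.approx(0.005)
        assert est.or_per_increment == pytest.approx(np.exp(0.25))
        assert round(est.or_per_increment, 2) == 1.28

    def test_per_50_scaling_of_small_log_or(self):
        est = ivw([50.0], [0.038], [0.01])
        assert round(est.or_per_increment, 2) == 1.04

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_zero_intercept_wls_oracle(self, seed):
        bx, by, se = _random_inputs(seed)
        est = IvwEstimator().fit(bx, by, se)
        fit = sm.WLS(by, bx[:, None], weights=1.0 / se ** 2).fit()
        assert est.theta_ == pytest.approx(fit.params[0], abs=1e-10)
        se_fixed = float(np.sqrt(fit.normalized_cov_params[0, 0]))
        assert est.se_theta_ == pytest.approx(se_fixed, abs=1e-10)

    def test_scale_equivariance(self):
        bx, by, se = _random_inputs(5)
        a = ivw(bx, by, se)
        b = ivw(10.0 * bx, by, se)
        assert b.theta == pytest.approx(a.theta / 10.0, rel=1e-12)
        # re-expressing apoB in new units leaves the OR per converted
        # increment unchanged
        assert np.exp(500.0 * b.theta) == pytest.approx(np.exp(50.0 * a.theta))

    def test_all_zero_exposure_betas_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ivw([0.0, 0.0], [0.1, 0.2], [0.05, 0.05])

    def test_random_effects_never_deflates_se(self):
        bx, by, se = _random_inputs(7)
        fe = IvwEstimator().fit(bx, by, se)
        re = IvwEstimator(random_effects=True).fit(bx, by, se)
        assert re.theta_ == fe.theta_
        assert re.se_theta_ >= fe.se_theta_

    def test_or_identity_holds_exactly(self):
        est = ivw(*_random_inputs(9))
        assert est.or_per_increment == np.exp(50.0 * est.theta)
        lo, hi = est.ci95_or_per_increment
        assert lo < est.or_per_increment < hi


class TestEgger:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        bx = np.array([5.0, 10.0, 20.0, 35.0, 50.0])
        by = 0.002 + 0.004 * bx
        est = EggerEstimator().fit(bx, by, np.full(5, 0.03))
        assert est.theta_ == pytest.approx(0.004, abs=1e-14)
        assert est.intercept_ == pytest.approx(0.002, abs=1e-14)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_intercept_wls_oracle(self, seed):
        bx, by, se = _random_inputs(seed)
        est = EggerEstimator().fit(bx, by, se)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / se ** 2).fit()
        assert est.intercept_ == pytest.approx(fit.params[0], abs=1e-10)
        assert est.theta_ == pytest.approx(fit.params[1], abs=1e-10)

    def test_orientation_to_nonnegative_exposure(self):
        bx = np.array([5.0, -10.0, 20.0, -35.0])
        by = 0.004 * bx + 0.001
        flipped = EggerEstimator().fit(bx, by, np.full(4, 0.03))
        manual = EggerEstimator().fit(np.abs(bx), np.sign(bx) * by,
                                      np.full(4, 0.03))
        assert flipped.theta_ == pytest.approx(manual.theta_, abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger([1.0, 2.0], [0.1, 0.2], [0.05, 0.05])

    def test_null_pleiotropy_intercept_calibrated(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 200
        for _ in range(reps):
            bx = rng.uniform(5, 40, 15)
            se = np.full(15, 0.03)
            by = 0.004 * bx + rng.normal(0, se)
            est = EggerEstimator().fit(bx, by, se)
            if abs(est.intercept_ / est.intercept_se_) < 2.0:
                hits += 1
        assert hits / reps >= 0.92


class TestWeightedMedian:
    def test_equal_ratios_recovered(self):
        bx = np.array([5.0, 10.0, 20.0])
        est = weighted_median(bx, 0.004 * bx, np.full(3, 0.02))
        assert est.theta == pytest.approx(0.004, abs=1e-12)

    def test_reduces_to_plain_median_with_symmetric_weights(self):
        bx = np.full(5, 10.0)
        ratios = np.array([0.001, 0.002, 0.004, 0.006, 0.009])
        est = weighted_median(bx, ratios * bx, np.full(5, 0.02))
        assert est.theta == pytest.approx(np.median(ratios), abs=1e-12)

    def test_robust_to_a_single_outlier(self):
        bx = np.full(10, 10.0)
        by = np.full(10, 0.04)   # consistent ratio 0.004
        by[0] = 0.4              # tenfold outlier
        est = weighted_median(bx, by, np.full(10, 0.02), seed=1)
        assert est.theta == pytest.approx(0.004, rel=0.05)

    def test_zero_exposure_instrument_dropped_with_warning(self):
        bx = np.array([0.0, 10.0, 20.0, 30.0])
        with pytest.warns(UserWarning, match="zero"):
            est = weighted_median(bx, 0.004 * bx, np.full(4, 0.02))
        assert est.n_snps == 3

    def test_bootstrap_se_reproducible(self):
        bx, by, se = _random_inputs(13)
        a = WeightedMedianEstimator(seed=5).fit(bx, by, se)
        b = WeightedMedianEstimator(seed=5).fit(bx, by, se)
        assert a.se_theta_ == b.se_theta_


class TestRunMrForCluster:
    @staticmethod
    def _cluster_and_stats(k=8, seed=0):
        rng = np.random.default_rng(seed)
        snps = [f"s{i}" for i in range(k)]
        weights = rng.uniform(5, 40, k)
        table = pd.DataFrame(
            {"effect_allele": "A", "other_allele": "G", "apob_weight": weights},
            index=pd.Index(snps, name="snp_id"),
        )
        cluster = SnpCluster("Lp(a)", table)
        mk = lambda betas, ses: pd.DataFrame(
            {"snp_id": snps, "effect_allele": "A", "other_allele": "G",
             "eaf": 0.3, "beta": betas, "se": ses,
             "pvalue": 1e-9, "n": 10_000, "trait": "x"}
        )
        assoc_apob = mk(weights, 1.5)
        assoc_chd = mk(0.004 * weights + rng.normal(0, 0.02, k), 0.02)
        return cluster, assoc_apob, assoc_chd

    def test_two_sample_with_own_stats_equals_one_sample(self):
        cluster, apob, chd = self._cluster_and_stats()
        one = run_mr_for_cluster(cluster, apob, chd)
        two = run_mr_for_cluster(cluster, apob, chd.copy())
        assert one["ivw"].theta == two["ivw"].theta

    def test_partial_outcome_overlap_runs_on_intersection(self):
        cluster, apob, chd = self._cluster_and_stats()
        partial = chd.iloc[:-2]
        with pytest.warns(UserWarning, match="intersection"):
            out = run_mr_for_cluster(cluster, apob, partial)
        assert out["ivw"].n_snps == len(cluster) - 2

    def test_allele_mismatch_is_hard_error_listing_snps(self):
        cluster, apob, chd = self._cluster_and_stats()
        chd.loc[0, "effect_allele"] = "C"
        chd.loc[0, "other_allele"] = "T"
        with pytest.raises(ClusterError, match="s0"):
            run_mr_for_cluster(cluster, apob, chd)

    def test_swapped_alleles_in_outcome_are_harmonised(self):
        cluster, apob, chd = self._cluster_and_stats()
        straight = run_mr_for_cluster(cluster, apob, chd)
        swapped = chd.copy()
        swapped["effect_allele"], swapped["other_allele"] = "G", "A"
        swapped["beta"] = -swapped["beta"]
        swapped["eaf"] = 1.0 - swapped["eaf"]
        out = run_mr_for_cluster(cluster, apob, swapped)
        assert out["ivw"].theta == pytest.approx(straight["ivw"].theta, rel=1e-12)

    def test_all_methods_agree_without_pleiotropy(self):
        cluster, apob, chd = self._cluster_and_stats(k=20, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_mr_for_cluster(cluster, apob, chd)
        th = out["ivw"].theta
        for m in ("egger", "weighted_median"):
            lo = out[m].theta - 2 * out[m].se_theta
            hi = out[m].theta + 2 * out[m].se_theta
            assert lo < th < hi
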