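"""Cluster construction rules, allele orientation and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from particle_mr.clusters import (ClusterError, beta_beta_diagnostic,
                                  build_ldl_cluster, build_lpa_cluster,
                                  harmonise_to_cluster, SnpCluster)


def _assoc(rows, trait):
    df = pd.DataFrame(rows)
    df["trait"] = trait
    for col, default in [("effect_allele", "A"), ("other_allele", "G"),
                         ("eaf", 0.3), ("se", 0.05), ("n", 10_000)]:
        if col not in df:
            df[col] = default
    return df


def _dosages(snp_ids, n=400, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({s: rng.binomial(2, 0.3, n).astype(float)
                         for s in snp_ids})


def _assoc_set(lpa_p, ldl_p, rem_p, tg_p, apob_beta, snp_ids,
               ldl_beta=None, rem_beta=None):
    mk = lambda ps, betas: _assoc(
        [{"snp_id": s, "beta": b, "pvalue": p}
         for s, p, b in zip(snp_ids, ps, betas)], "x")
    k = len(snp_ids)
    return {
        "lpa_mass": mk(lpa_p, [10.0] * k),
        "ldl_c": mk(ldl_p, ldl_beta if ldl_beta is not None else [0.4] * k),
        "remnant_c": mk(rem_p, rem_beta if rem_beta is not None else [0.01] * k),
        "triglycerides": mk(tg_p, [0.02] * k),
        "apob_molar": mk([1e-12] * k, apob_beta),
    }


class TestLpaCluster:
    def test_clean_snp_retained_pleiotropic_snp_removed(self):
        snps = ["clean", "pleio"]
        assoc = _assoc_set(
            lpa_p=[1e-20, 1e-20], ldl_p=[0.5, 1e-12], rem_p=[0.5, 0.5],
            tg_p=[0.5, 0.5], apob_beta=[12.0, 15.0], snp_ids=snps,
        )
        cluster = build_lpa_cluster(assoc, _dosages(snps))
        assert cluster.snp_ids == ["clean"]
        prov = cluster.provenance.set_index("snp_id")["rule"]
        assert prov["pleio"] == "pleiotropy_ldl_c"
        assert prov["clean"] == "retained"

    def test_empty_cluster_raises_with_provenance(self):
        assoc = _assoc_set([0.9], [0.5], [0.5], [0.5], [1.0], ["only"])
        with pytest.raises(ClusterError, match="provenance"):
            build_lpa_cluster(assoc, _dosages(["only"]))

    def test_full_simulation_recovers_only_lpa_locus(self, small_cohort,
                                                     small_associations):
        cluster = build_lpa_cluster(small_associations, small_cohort.genotypes)
        loci = small_cohort.snps.loc[cluster.snp_ids, "locus"]
        assert (loci == "LPA").all()
        assert len(cluster) >= 3


class TestLdlCluster:
    def test_remnant_ratio_rule(self):
        snps = ["keep", "drop"]
        assoc = _assoc_set(
            lpa_p=[0.9, 0.9], ldl_p=[1e-12, 1e-12], rem_p=[0.5, 0.5],
            tg_p=[0.5, 0.5], apob_beta=[30.0, 30.0], snp_ids=snps,
            ldl_beta=[0.40, 1.00], rem_beta=[0.02, 0.20],
        )
        cluster = build_ldl_cluster(assoc, _dosages(snps))
        assert cluster.snp_ids == ["keep"]  # 0.05 <= 0.15 kept, 0.20 dropped
        prov = cluster.provenance.set_index("snp_id")["rule"]
        assert prov["drop"] == "remnant_ratio"

    def test_lpa_significant_snp_excluded_regardless_of_ratio(self):
        snps = ["ldl_like", "lpa_like"]
        assoc = _assoc_set(
            lpa_p=[0.9, 1e-30], ldl_p=[1e-12, 1e-12], rem_p=[0.5, 0.5],
            tg_p=[0.5, 0.5], apob_beta=[30.0, 30.0], snp_ids=snps,
        )
        cluster = build_ldl_cluster(assoc, _dosages(snps))
        assert cluster.snp_ids == ["ldl_like"]
        assert cluster.provenance.set_index("snp_id").at["lpa_like", "rule"] \
            == "lpa_significant"

    def test_unstable_ldl_beta_excluded(self):
        snps = ["stable", "unstable"]
        assoc = _assoc_set(
            lpa_p=[0.9, 0.9], ldl_p=[1e-12, 1e-12], rem_p=[0.5, 0.5],
            tg_p=[0.5, 0.5], apob_beta=[30.0, 30.0], snp_ids=snps,
            ldl_beta=[0.40, 0.03],  # |beta| <= se (0.05) is unstable
        )
        cluster = build_ldl_cluster(assoc, _dosages(snps))
        assert cluster.snp_ids == ["stable"]
        assert cluster.provenance.set_index("snp_id").at["unstable", "rule"] \
            == "unstable_ldl_beta"

    def test_clusters_are_disjoint_on_simulation(self, small_cohort,
                                                 small_associations):
        lpa = build_lpa_cluster(small_associations, small_cohort.genotypes)
        ldl = build_ldl_cluster(small_associations, small_cohort.genotypes)
        assert not set(lpa.snp_ids) & set(ldl.snp_ids)
        loci = small_cohort.snps.loc[ldl.snp_ids, "locus"]
        assert (loci != "NULL").all()
        lpa_loci = small_cohort.snps.loc[lpa.snp_ids, "locus"]
        assert (lpa_loci != "NULL").all()


class TestOrientation:
    def test_negative_apob_beta_flipped_to_raising_allele(self):
        snps = ["pos", "neg"]
        assoc = _assoc_set([1e-20, 1e-20], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5],
                           apob_beta=[12.0, -8.0], snp_ids=snps)
        cluster = build_lpa_cluster(assoc, _dosages(snps))
        assert (cluster.apob_weights >= 0).all()
        assert cluster.table.at["neg", "effect_allele"] == "G"
        assert cluster.table.at["neg", "apob_weight"] == pytest.approx(8.0)

    def test_orientation_idempotence_under_allele_recoding(self):
        snps = ["s1", "s2"]
        assoc = _assoc_set([1e-20, 1e-20], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5],
                           apob_beta=[12.0, -8.0], snp_ids=snps)
        flipped = {t: df.copy() for t, df in assoc.items()}
        for df in flipped.values():
            df["beta"] = -df["beta"]
            df["effect_allele"], df["other_allele"] = "G", "A"
            df["eaf"] = 1.0 - df["eaf"]
        a = build_lpa_cluster(assoc, _dosages(snps))
        b = build_lpa_cluster(flipped, _dosages(snps))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_harmonise_rejects_irreconcilable_alleles(self):
        table = pd.DataFrame(
            {"effect_allele": ["A"], "other_allele": ["G"], "apob_weight": [5.0]},
            index=pd.Index(["s1"], name="snp_id"),
        )
        cluster = SnpCluster("Lp(a)", table)
        assoc = _assoc([{"snp_id": "s1", "beta": 1.0, "pvalue": 0.1}], "chd")
        assoc["effect_allele"], assoc["other_allele"] = "C", "T"
        with pytest.raises(ClusterError, match="s1"):
            harmonise_to_cluster(cluster, assoc)


class TestBetaBetaDiagnostic:
    def _cluster(self, snps, weights):
        table = pd.DataFrame(
            {"effect_allele": "A", "other_allele": "G", "apob_weight": weights},
            index=pd.Index(snps, name="snp_id"),
        )
        return SnpCluster("Lp(a)", table)

    def test_identical_beta_vectors_give_slope_one(self):
        snps = ["a", "b", "c", "d"]
        betas = [5.0, 10.0, 20.0, 40.0]
        assoc = _assoc([{"snp_id": s, "beta": b, "pvalue": 1e-9}
                        for s, b in zip(snps, betas)], "x")
        out = beta_beta_diagnostic(self._cluster(snps, betas), assoc, assoc)
        assert out["slope"] == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_three_snps_skips_with_warning(self):
        snps = ["a", "b"]
        assoc = _assoc([{"snp_id": s, "beta": 1.0, "pvalue": 1e-9} for s in snps], "x")
        with pytest.warns(UserWarning, match="skipped"):
            assert beta_beta_diagnostic(self._cluster(snps, [1.0, 1.0]),
                                        assoc, assoc) is None

    def test_ldl_cluster_has_near_zero_lpa_slope(self, small_cohort,
                                                 small_associations):
        ldl = build_ldl_cluster(small_associations, small_cohort.genotypes)
        out = beta_beta_diagnostic(ldl, small_associations["lpa_mass"],
                                   small_associations["apob_molar"])
        assert abs(out["slope"]) < 2.0 * out["se"] + 0.05
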