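"""Replicate studies for parameter recovery and null calibration.

These helpers run the simulate -> GWAS -> cluster -> MR -> quotient chain
many times at desk scale and summarise recovery of the generating
per-particle effects.  The desk-scale design halves the cohort (n = 25,000)
and halves the variant counts while leaving the per-particle effects and
the trait architecture (total genetic variances, LD blocks, noise scales)
unchanged; per-instrument z-scores and the errors-in-variables budget are
then the same as at the full default scale, so the half-scale replicate
distribution is representative of the full design.

The CHD scan inside a replicate is restricted to the selected cluster SNPs
(the only outcome betas the MR stage consumes), which keeps a replicate
under two seconds without changing any estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clusters import build_ldl_cluster, build_lpa_cluster
from .gwas import associate
from .mr import run_mr_for_cluster
from .quotient import bootstrap_ci
from .simulate import SimulationConfig, simulate_cohort

QUANT_TRAITS = ("lpa_mass", "apob_molar", "ldl_c", "remnant_c", "triglycerides")


def half_scale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Half-size replicate cohort: 25,000 subjects, variant counts halved."""
    base = dict(
        n_subjects=25_000,
        n_lpa_locus_snps=100,
        n_ldl_snps=75,
        n_null_snps=50,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def quotient_replicate(config: SimulationConfig, n_boot: int = 4000) -> dict:
    """One replicate: full selection + MR chain, returns quotient and thetas."""
    cohort = simulate_cohort(config)
    assoc = {t: associate(cohort, t) for t in QUANT_TRAITS}
    lpa = build_lpa_cluster(assoc, cohort.genotypes)
    ldl = build_ldl_cluster(assoc, cohort.genotypes)
    cluster_snps = lpa.snp_ids + ldl.snp_ids
    assoc_chd = associate(cohort, "chd", subject_filter="all",
                          snp_ids=cluster_snps)
    mr_lpa = run_mr_for_cluster(lpa, assoc["apob_molar"], assoc_chd,
                                seed=config.seed)
    mr_ldl = run_mr_for_cluster(ldl, assoc["apob_molar"], assoc_chd,
                                seed=config.seed + 1)
    rq = bootstrap_ci(mr_lpa["ivw_re"], mr_ldl["ivw_re"], n_boot=n_boot,
                      seed=config.seed, method="parametric")
    truth = config.true_quotient
    return {
        "seed": config.seed,
        "quotient": rq.q,
        "ci_lo": rq.ci95[0],
        "ci_hi": rq.ci95[1],
        "covers_truth": bool(rq.ci95[0] <= truth <= rq.ci95[1]),
        "theta_lpa": mr_lpa["ivw"].theta,
        "theta_ldl": mr_ldl["ivw"].theta,
        "se_theta_lpa": mr_lpa["ivw"].se_theta,
        "se_theta_ldl": mr_ldl["ivw"].se_theta,
        "n_snps_lpa": len(lpa),
        "n_snps_ldl": len(ldl),
        "true_quotient": truth,
    }


def quotient_replicate_study(n_replicates: int, seed: int = 0,
                             n_boot: int = 4000, **config_overrides) -> pd.DataFrame:
    """Independent half-scale replicates; one row per replicate."""
    rows = []
    for i in range(n_replicates):
        cfg = half_scale_config(seed=seed + i, **config_overrides)
        rows.append(quotient_replicate(cfg, n_boot=n_boot))
    return pd.DataFrame(rows)


def summarise_recovery(study: pd.DataFrame) -> dict:
    """Mean quotient, relative bias against truth, and CI coverage."""
    truth = float(study["true_quotient"].iloc[0])
    mean_q = float(study["quotient"].mean())
    return {
        "n_replicates": int(len(study)),
        "true_quotient": truth,
        "mean_quotient": mean_q,
        "relative_bias": mean_q / truth - 1.0,
        "coverage": float(study["covers_truth"].mean()),
        "mean_theta_lpa": float(study["theta_lpa"].mean()),
        "mean_theta_ldl": float(study["theta_ldl"].mean()),
    }


def null_gwas_pvalues(seed: int = 0, n_subjects: int = 8000,
                      traits=("apob_molar", "ldl_c", "chd")) -> np.ndarray:
    """Pooled per-SNP p-values under a cohort with no genetic effects.

    All genetic effect sizes are zero (the LPA locus explains no variance
    and the LDL variants have no effect), so every SNP x trait test is null
    and the pooled p-values should be uniform on (0, 1).
    """
    cfg = half_scale_config(
        seed=seed,
        n_subjects=n_subjects,
        lpa_log_genetic_var=0.0,
        ldl_genetic_sd=0.0,
        lpa_locus_ld_rho=0.0,  # independent nulls for a clean uniformity test
    )
    cohort = simulate_cohort(cfg)
    pooled = []
    for t in traits:
        kw = {"subject_filter": "all"} if t == "chd" else {}
        pooled.append(associate(cohort, t, **kw)["pvalue"].to_numpy())
    return np.concatenate(pooled)


def equal_effects_study(n_replicates: int, seed: int = 0,
                        n_boot: int = 4000) -> pd.DataFrame:
    """Replicates with equal per-particle effects (true quotient 1)."""
    theta = SimulationConfig().true_log_or_per_nmol_lpa
    return quotient_replicate_study(
        n_replicates, seed=seed, n_boot=n_boot,
        true_log_or_per_nmol_ldl=theta,
    )
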