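"""End-to-end analysis pipeline and the worked-examples runner.

``run_pipeline`` executes simulate -> per-trait GWAS -> cluster selection ->
Mendelian randomisation -> polygenic-score/Cox analysis -> risk quotient,
with a sensitivity re-selection at a stricter LD threshold and a comparison
of the estimated quotient against the generator's ground truth.  The report
is a plain JSON-serialisable dict; each stage's payload also carries a
sha256 content hash so a re-run can be audited stage by stage.

``worked_examples`` recomputes the handful of headline numbers that are
pure arithmetic on published summary values (risk quotients from pairs of
log odds ratios, odds ratios from per-50-nmol/L log odds ratios, and the
mass-to-molar unit conversions) and checks them against the expected
printed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import units
from .clusters import beta_beta_diagnostic, build_ldl_cluster, build_lpa_cluster
from .gwas import (DEFAULT_GWAS_COVARIATES, MAF_THRESHOLD, P_THRESHOLD,
                   R2_THRESHOLD, associate)
from .io import write_summary_stats
from .mr import MrEstimate, run_mr_for_cluster
from .pgs import DEFAULT_COX_COVARIATES, compute_pgs, cox_hr_per_50
from .quotient import bootstrap_ci, quotient as quotient_of_estimates
from .simulate import SimulationConfig, heldout_truth_check, simulate_cohort

QUANT_TRAITS = ("lpa_mass", "apob_molar", "ldl_c", "remnant_c", "triglycerides")


def _default_thresholds() -> dict:
    return {
        "p": P_THRESHOLD,
        "maf": MAF_THRESHOLD,
        "r2": R2_THRESHOLD,
        "remnant_ratio_max": 0.15,
        "pleiotropy_p": P_THRESHOLD,
    }


def _default_bootstrap() -> dict:
    return {"method": "parametric", "n_boot": 100_000, "seed": 1}


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; round-trips through YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: dict = field(default_factory=_default_thresholds)
    scale_nmol: float = 50.0
    covariates_gwas: tuple = DEFAULT_GWAS_COVARIATES
    covariates_cox: tuple = DEFAULT_COX_COVARIATES
    bootstrap: dict = field(default_factory=_default_bootstrap)
    include_pgs: bool = True
    include_sensitivity: bool = True
    sensitivity_r2: float = 0.01
    output_dir: str | None = None

    def validate(self) -> "PipelineConfig":
        for k, v in self.thresholds.items():
            if not v > 0:
                raise ValueError(f"threshold {k!r} must be positive, got {v}")
        self.simulation.validate()
        return self

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["covariates_gwas"] = list(self.covariates_gwas)
        d["covariates_cox"] = list(self.covariates_cox)
        for key in ("maf_range", "lpa_skew_params", "assay_range"):
            d["simulation"][key] = list(d["simulation"][key])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if os.path.exists(str(source)):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(source)
        sim = d.pop("simulation", {})
        for key in ("maf_range", "lpa_skew_params", "assay_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg = cls(simulation=SimulationConfig(**sim), **{
            k: (tuple(v) if k.startswith("covariates_") else v)
            for k, v in d.items()
        })
        return cfg.validate()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_list())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def _content_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(_jsonify(payload), sort_keys=True).encode()
    ).hexdigest()


def _cluster_payload(cluster) -> dict:
    rules = cluster.provenance["rule"].value_counts().to_dict() \
        if len(cluster.provenance) else {}
    return {
        "name": cluster.name,
        "n_snps": len(cluster),
        "snp_ids": cluster.snp_ids,
        "apob_weights": cluster.apob_weights.tolist(),
        "provenance_rule_counts": rules,
    }


def _select_clusters(assoc, dosages, thresholds, r2):
    lpa = build_lpa_cluster(
        assoc, dosages,
        p_threshold=thresholds["p"], maf_threshold=thresholds["maf"],
        r2_threshold=r2, pleiotropy_p=thresholds["pleiotropy_p"],
    )
    ldl = build_ldl_cluster(
        assoc, dosages,
        p_threshold=thresholds["p"], maf_threshold=thresholds["maf"],
        r2_threshold=r2, pleiotropy_p=thresholds["pleiotropy_p"],
        remnant_ratio_max=thresholds["remnant_ratio_max"],
    )
    return lpa, ldl


def run_pipeline(config: PipelineConfig | None = None,
                 external_outcome_stats: pd.DataFrame | None = None) -> dict:
    """Run the full analysis on a freshly simulated cohort; returns the report.

    With ``external_outcome_stats`` the MR stage additionally runs in
    two-sample mode against the supplied CHD summary statistics.
    """
    cfg = (config or PipelineConfig()).validate()
    report: dict = {"config_yaml": cfg.to_yaml(), "stages": {}}

    def record(stage: str, payload: dict):
        payload = _jsonify(payload)
        report["stages"][stage] = {"payload": payload,
                                   "sha256": _content_hash(payload)}
        return payload

    # 1. simulate ---------------------------------------------------------
    cohort = simulate_cohort(cfg.simulation)
    truth = heldout_truth_check(cohort)
    record("simulate", {
        "n_subjects": cohort.n_subjects,
        "n_snps": cohort.n_snps,
        "n_prevalent": cohort.manifest["n_prevalent"],
        "n_incident": cohort.manifest["n_incident"],
        "true_quotient": cohort.manifest["true_quotient"],
        "truth_check": truth,
    })

    # 2. per-trait association scans -------------------------------------
    assoc = {t: associate(cohort, t, covariates=cfg.covariates_gwas)
             for t in QUANT_TRAITS}
    assoc["chd"] = associate(cohort, "chd", covariates=cfg.covariates_gwas,
                             subject_filter="all")
    record("gwas", {
        "covariates": list(cfg.covariates_gwas),
        "subject_filter": {"quantitative": "untreated_with_lipids", "chd": "all"},
        "n_tested": {t: int(len(a)) for t, a in assoc.items()},
        "n_genome_wide_significant": {
            t: int((a["pvalue"] < cfg.thresholds["p"]).sum())
            for t, a in assoc.items()
        },
    })

    # 3. cluster selection ------------------------------------------------
    lpa_cluster, ldl_cluster = _select_clusters(
        assoc, cohort.genotypes, cfg.thresholds, cfg.thresholds["r2"]
    )
    overlap = set(lpa_cluster.snp_ids) & set(ldl_cluster.snp_ids)
    if overlap:
        raise RuntimeError(f"clusters are not disjoint: {sorted(overlap)[:5]!r}")
    record("clusters", {
        "lpa": _cluster_payload(lpa_cluster),
        "ldl": _cluster_payload(ldl_cluster),
    })

    # 4. Mendelian randomisation -----------------------------------------
    mr_lpa = run_mr_for_cluster(lpa_cluster, assoc["apob_molar"], assoc["chd"],
                                scale_nmol=cfg.scale_nmol,
                                seed=cfg.simulation.seed + 101)
    mr_ldl = run_mr_for_cluster(ldl_cluster, assoc["apob_molar"], assoc["chd"],
                                scale_nmol=cfg.scale_nmol,
                                seed=cfg.simulation.seed + 102)
    mr_payload = {
        "lpa": {m: est.to_dict() for m, est in mr_lpa.items()},
        "ldl": {m: est.to_dict() for m, est in mr_ldl.items()},
        "design": "one-sample (exposure betas from untreated subjects, "
                  "outcome log ORs from all subjects)",
    }
    if external_outcome_stats is not None:
        mr_lpa_ext = run_mr_for_cluster(lpa_cluster, assoc["apob_molar"],
                                        external_outcome_stats,
                                        scale_nmol=cfg.scale_nmol)
        mr_ldl_ext = run_mr_for_cluster(ldl_cluster, assoc["apob_molar"],
                                        external_outcome_stats,
                                        scale_nmol=cfg.scale_nmol)
        mr_payload["two_sample"] = {
            "lpa": {m: est.to_dict() for m, est in mr_lpa_ext.items()},
            "ldl": {m: est.to_dict() for m, est in mr_ldl_ext.items()},
        }
    record("mr", mr_payload)

    # 5. polygenic scores + Cox ------------------------------------------
    diagnostics: dict = {}
    if cfg.include_pgs:
        pgs_payload = {}
        for cluster in (lpa_cluster, ldl_cluster):
            scores = compute_pgs(cohort, cluster)
            res = cox_hr_per_50(scores, cohort, covariates=cfg.covariates_cox,
                                scale_nmol=cfg.scale_nmol)
            res.cluster_name = cluster.name
            pgs_payload[cluster.name] = res.to_dict()
            if cluster.name == "Lp(a)":
                vent = res.ventile_summaries
                diagnostics["lpa_ventile_mean_lpa_mass"] = \
                    vent["mean_lpa_mass"].tolist()
                diagnostics["lpa_ventile_mean_apob"] = \
                    vent["mean_apob_molar"].tolist()
                diffs = np.diff(vent["mean_lpa_mass"].to_numpy())
                diagnostics["lpa_ventile_monotone_increasing"] = bool(
                    np.all(diffs > 0)
                )
                x = vent["mean_lpa_mass"].to_numpy()
                y = vent["mean_apob_molar"].to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                diagnostics["ventile_apob_on_lpa_slope"] = float(
                    xc @ yc / (xc @ xc)
                )
        record("pgs", pgs_payload)

    # 6. risk quotient ----------------------------------------------------
    # bootstrap draws use the heterogeneity-inflated (multiplicative
    # random-effects) SEs; the point estimate equals the fixed-effect IVW
    rq = bootstrap_ci(
        mr_lpa["ivw_re"], mr_ldl["ivw_re"],
        n_boot=cfg.bootstrap["n_boot"], seed=cfg.bootstrap["seed"],
        method=cfg.bootstrap["method"],
    )
    true_q = cohort.manifest["true_quotient"]
    record("quotient", {
        **rq.to_dict(),
        "ground_truth": {
            "true_quotient": true_q,
            "ci_covers_truth": bool(rq.ci95[0] <= true_q <= rq.ci95[1]),
        },
    })

    # 7. diagnostics (beta-beta agreement) --------------------------------
    # betas for both traits recomputed on the matched complete-panel sample
    # so the Lp(a) assay-range truncation cancels and the regression tests
    # the one-mole-per-mole identity itself; the apoB scan additionally
    # adjusts for LDL-C and triglycerides, isolating the Lp(a)-attributable
    # apoB signal (pure variance reduction for LPA-locus variants, which are
    # independent of the other lipid fractions)
    diag_snps = list(dict.fromkeys(lpa_cluster.snp_ids + ldl_cluster.snp_ids))
    assoc_lpa_m = associate(cohort, "lpa_mass", covariates=cfg.covariates_gwas,
                            subject_filter="untreated_complete_panel",
                            snp_ids=diag_snps)
    assoc_apob_m = associate(cohort, "apob_molar",
                             covariates=tuple(cfg.covariates_gwas)
                             + ("ldl_c", "triglycerides"),
                             subject_filter="untreated_complete_panel",
                             snp_ids=diag_snps)
    bb_lpa = beta_beta_diagnostic(lpa_cluster, assoc_lpa_m, assoc_apob_m)
    bb_ldl = beta_beta_diagnostic(ldl_cluster, assoc_lpa_m, assoc_apob_m)
    if bb_lpa is not None:
        diagnostics["lpa_beta_beta_slope"] = bb_lpa["slope"]
        diagnostics["lpa_beta_beta_se"] = bb_lpa["se"]
    if bb_ldl is not None:
        diagnostics["ldl_beta_beta_slope"] = bb_ldl["slope"]
        diagnostics["ldl_beta_beta_se"] = bb_ldl["se"]
    record("diagnostics", diagnostics)

    # 8. sensitivity: stricter LD pruning ---------------------------------
    if cfg.include_sensitivity:
        lpa_s, ldl_s = _select_clusters(
            assoc, cohort.genotypes, cfg.thresholds, cfg.sensitivity_r2
        )
        mr_lpa_s = run_mr_for_cluster(lpa_s, assoc["apob_molar"], assoc["chd"],
                                      scale_nmol=cfg.scale_nmol)
        mr_ldl_s = run_mr_for_cluster(ldl_s, assoc["apob_molar"], assoc["chd"],
                                      scale_nmol=cfg.scale_nmol)
        rq_s = bootstrap_ci(mr_lpa_s["ivw_re"], mr_ldl_s["ivw_re"],
                            n_boot=cfg.bootstrap["n_boot"],
                            seed=cfg.bootstrap["seed"],
                            method=cfg.bootstrap["method"])
        record("sensitivity_r2", {
            "r2_threshold": cfg.sensitivity_r2,
            "lpa_n_snps": len(lpa_s),
            "ldl_n_snps": len(ldl_s),
            "or_per_increment_lpa": mr_lpa_s["ivw"].or_per_increment,
            "or_per_increment_ldl": mr_ldl_s["ivw"].or_per_increment,
            "quotient": rq_s.q,
            "ci95": list(rq_s.ci95),
            "main_ci_contains_sensitivity_quotient": bool(
                rq.ci95[0] <= rq_s.q <= rq.ci95[1]
            ),
        })

    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        for t, a in assoc.items():
            write_summary_stats(a, os.path.join(cfg.output_dir, f"gwas_{t}.tsv"))
        for cl in (lpa_cluster, ldl_cluster):
            name = "lpa" if cl.name == "Lp(a)" else "ldl"
            cl.table.reset_index().assign(
                source_rule="retained"
            ).to_csv(os.path.join(cfg.output_dir, f"cluster_{name}.tsv"),
                     sep="\t", index=False)
        with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return report


# ---------------------------------------------------------------------------
# worked examples: arithmetic on published summary values
# ---------------------------------------------------------------------------

def _round_sig(x: float, n: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def _quotient_from_log_ors(log_or_lpa: float, log_or_ldl: float) -> float:
    est_lpa = MrEstimate("Lp(a)", "ivw", log_or_lpa / 50.0, 0.0, 1)
    est_ldl = MrEstimate("LDL", "ivw", log_or_ldl / 50.0, 0.0, 1)
    return quotient_of_estimates(est_lpa, est_ldl)


#: name -> (computation, expected printed value, how it is rounded)
_WORKED_EXAMPLES = {
    "risk_quotient_ukb_present_snp_set": (
        lambda: _quotient_from_log_ors(0.25, 0.038), 6.6, ("decimals", 1)),
    "risk_quotient_ukb_previous_snp_set": (
        lambda: _quotient_from_log_ors(0.45, 0.038), 11.8, ("decimals", 1)),
    "risk_quotient_cardiogram": (
        lambda: _quotient_from_log_ors(0.15, 0.040), 3.8, ("decimals", 1)),
    "or_per_50_nmol_lpa_apob": (
        lambda: math.exp(0.25), 1.28, ("decimals", 2)),
    "or_per_50_nmol_ldl_apob": (
        lambda: math.exp(0.038), 1.04, ("decimals", 2)),
    "apob_1p03_g_l_in_nmol_l": (
        lambda: units.convert_apob_mass_to_molar(1.03), 1870.0, ("sigfig", 3)),
    "lpa_101p5_mg_dl_in_nmol_l": (
        lambda: units.convert_lpa_mass_to_molar(101.5), 220.0, ("sigfig", 2)),
    "lpa_55_mg_dl_in_nmol_l": (
        lambda: units.convert_lpa_mass_to_molar(55.0), 120.0, ("sigfig", 2)),
}


def worked_examples(names=None, expected_overrides: dict | None = None) -> pd.DataFrame:
    """Recompute published-arithmetic checks; one row per check.

    ``names`` selects a subset (an empty list gives an empty table);
    ``expected_overrides`` substitutes expected values, which makes the
    harness itself testable: a corrupted constant must show up as a failure
    with the computed-vs-expected difference.
    """
    selected = _WORKED_EXAMPLES if names is None else {
        k: _WORKED_EXAMPLES[k] for k in names
    }
    overrides = expected_overrides or {}
    rows = []
    for name, (fn, expected, (mode, digits)) in selected.items():
        expected = overrides.get(name, expected)
        value = float(fn())
        shown = round(value, digits) if mode == "decimals" else _round_sig(value, digits)
        rows.append(
            {
                "name": name,
                "computed": value,
                "computed_rounded": shown,
                "expected": expected,
                "passed": bool(np.isclose(shown, expected, rtol=0, atol=1e-12)),
                "diff": shown - expected,
            }
        )
    return pd.DataFrame(rows, columns=["name", "computed", "computed_rounded",
                                       "expected", "passed", "diff"])
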