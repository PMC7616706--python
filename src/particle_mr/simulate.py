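"""Synthetic cohort generator with known per-particle ground truth.

The generator emulates the genetic and lipoprotein architecture that the
Lp(a)-versus-LDL comparison relies on:

* a dense **LPA locus**: many variants in autoregressive LD whose effects act
  on the log of the Lp(a) particle concentration, so the marginal Lp(a)
  distribution is right-skewed (mean > median);
* an independent **polygenic LDL** architecture: unlinked variants with
  additive effects on the LDL particle concentration;
* **null** variants with no effect on anything;
* the structural identity *one apoB per particle*: latent molar apoB is the
  exact sum of Lp(a), LDL and VLDL particle concentrations, and Lp(a) mass
  in nmol/L equals the Lp(a) particle concentration one-to-one;
* CHD risk that is log-linear in the particle concentrations with a
  configurable per-particle effect ratio (the ground-truth risk quotient);
* assay censoring of measured Lp(a) outside the working range; and
* a lipid-lowering-therapy flag that perturbs *measured* (not latent)
  LDL-C and apoB, so that excluding treated subjects removes the bias.

Genetic effect sizes are drawn from a log-normal (magnitude) distribution
and then rescaled so that the locus explains a configured amount of trait
variance.  Scaling the cohort down (fewer subjects *and* proportionally
fewer variants) therefore preserves per-variant instrument strength, which
is what makes desk-scale replicate studies faithful to the full-size design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .io import Cohort
from .units import apply_assay_censoring, convert_apob_molar_to_mass


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


def _default_noise_sds() -> dict:
    return {
        "lpa_log": 0.22,        # residual sd of log Lp(a) particles
        "ldl_particle": 70.0,   # nmol/L, residual sd of LDL particles
        "vldl_particle": 30.0,  # nmol/L, sd of VLDL particles
        "apob": 12.0,           # nmol/L, apoB assay noise
        "ldl_c": 0.10,          # mmol/L
        "remnant_c": 0.04,      # mmol/L
        "hdl_c": 0.28,          # mmol/L
        "triglycerides": 0.25,  # mmol/L
    }


def _default_baseline_particles() -> dict:
    return {"ldl": 1650.0, "vldl": 170.0}


def _default_covariate_risk_effects() -> dict:
    # log-odds per unit of the (centred) covariate
    return {"age": 0.05, "sex": 0.45, "bmi": 0.02, "sbp": 0.008,
            "pc1": 0.03, "pc2": -0.02, "pc3": 0.02, "pc4": 0.0, "pc5": 0.0}


def _default_covariate_lipid_effects() -> dict:
    # effect on LDL particle concentration (nmol/L) per unit centred covariate
    return {"age": 2.5, "sex": -25.0, "bmi": 4.0, "pc1": 6.0, "pc2": -4.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    The ratio ``true_log_or_per_nmol_lpa / true_log_or_per_nmol_ldl`` is the
    ground-truth CHD risk quotient and is recorded in the output manifest.
    """

    n_subjects: int = 50_000
    n_lpa_locus_snps: int = 200
    n_ldl_snps: int = 150
    n_null_snps: int = 500
    lpa_locus_ld_rho: float = 0.96
    lpa_locus_block_size: int = 10
    maf_range: tuple = (0.05, 0.5)
    # per-particle log odds ratios (per nmol/L apoB in each particle class)
    true_log_or_per_nmol_lpa: float = 0.25 / 50.0
    true_log_or_per_nmol_ldl: float = 0.25 / 50.0 / 6.6
    # magnitudes of LPA-locus effects on log Lp(a): LogNormal(mu, sigma),
    # random sign, rescaled so the locus explains lpa_log_genetic_var
    lpa_skew_params: tuple = (-2.0, 0.6)
    lpa_log_genetic_var: float = 0.25
    lpa_log_median: float = math.log(36.0)
    ldl_genetic_sd: float = 150.0        # nmol/L explained by the LDL variants
    baseline_particles: dict = field(default_factory=_default_baseline_particles)
    noise_sds: dict = field(default_factory=_default_noise_sds)
    # cholesterol / triglyceride content per particle (mmol/L per nmol/L)
    chol_per_ldl_particle: float = 3.56 / 1650.0
    chol_per_vldl_particle: float = 0.80 / 170.0
    tg_per_vldl_particle: float = 1.50 / 170.0
    hdl_c_mean: float = 1.45
    treated_fraction: float = 0.17
    treatment_ldl_multiplier: float = 0.70
    followup_years: float = 12.0         # mean; realised follow-up uniform +-2 y
    assay_range: tuple = (3.8, 189.0)
    chd_logit_intercept: float = -2.10   # combined prevalent+incident endpoint
    prevalent_fraction_of_cases: float = 0.45
    incident_baseline_hazard: float = 0.004   # events / person-year
    covariate_risk_effects: dict = field(default_factory=_default_covariate_risk_effects)
    covariate_lipid_effects: dict = field(default_factory=_default_covariate_lipid_effects)
    seed: int = 0

    @property
    def true_quotient(self) -> float:
        return self.true_log_or_per_nmol_lpa / self.true_log_or_per_nmol_ldl

    def validate(self) -> "SimulationConfig":
        for name in ("n_subjects", "n_lpa_locus_snps", "n_ldl_snps", "n_null_snps"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.lpa_locus_ld_rho < 1.0:
            raise ConfigError("lpa_locus_ld_rho must be in [0, 1)")
        if self.lpa_locus_block_size <= 0:
            raise ConfigError("lpa_locus_block_size must be positive")
        if self.lpa_log_genetic_var < 0 or self.ldl_genetic_sd < 0:
            raise ConfigError("genetic variance parameters must be >= 0")
        if any(v < 0 for v in self.noise_sds.values()):
            raise ConfigError("noise sds must be >= 0")
        if min(self.baseline_particles.get("ldl", 0), self.baseline_particles.get("vldl", 0)) <= 0:
            raise ConfigError("baseline particle concentrations must be positive")
        if not 0.0 <= self.treated_fraction <= 1.0:
            raise ConfigError("treated_fraction must be in [0, 1]")
        if self.treatment_ldl_multiplier <= 0:
            raise ConfigError("treatment_ldl_multiplier must be positive")
        if not self.assay_range[0] < self.assay_range[1]:
            raise ConfigError("assay_range lower bound must be below upper bound")
        if self.followup_years <= 2.0:
            raise ConfigError("mean followup_years must exceed 2 (realised follow-up is mean +- 2)")
        if self.true_log_or_per_nmol_ldl == 0:
            raise ConfigError("true_log_or_per_nmol_ldl must be nonzero (quotient undefined)")
        return self


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort under ``config``; ground truth in ``cohort.manifest``.

    The latent particle table (Lp(a), LDL, VLDL, apoB and the linear risk
    score, all before measurement noise and treatment perturbation) is kept
    on the returned cohort as ``cohort.latents`` for truth checks.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    m1, m2, m0 = cfg.n_lpa_locus_snps, cfg.n_ldl_snps, cfg.n_null_snps

    # --- genotypes -------------------------------------------------------
    lo, hi = cfg.maf_range
    maf_lpa = rng.uniform(lo, hi, m1)
    maf_ldl = rng.uniform(lo, hi, m2)
    maf_null = rng.uniform(lo, hi, m0)

    # LPA locus: Gaussian-copula haplotypes with AR(1) LD decaying within
    # haplotype blocks and independence across block boundaries
    thr = ndtri(maf_lpa)
    rho, c = cfg.lpa_locus_ld_rho, math.sqrt(1.0 - cfg.lpa_locus_ld_rho ** 2)
    bs = cfg.lpa_locus_block_size
    g_lpa = np.zeros((n, m1))
    for _ in range(2):  # two haplotypes per subject
        z = np.empty((n, m1))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, m1 - 1)) if m1 > 1 else None
        for j in range(1, m1):
            if j % bs == 0:  # new block: restart the chain
                z[:, j] = rng.standard_normal(n)
            else:
                z[:, j] = rho * z[:, j - 1] + c * innov[:, j - 1]
        g_lpa += z < thr
    g_ldl = rng.binomial(2, maf_ldl, size=(n, m2)).astype(float)
    g_null = rng.binomial(2, maf_null, size=(n, m0)).astype(float)

    # --- genetic effects -------------------------------------------------
    mu_b, sd_b = cfg.lpa_skew_params
    b_raw = rng.lognormal(mu_b, sd_b, m1) * rng.choice([-1.0, 1.0], m1)
    het_lpa = 2.0 * maf_lpa * (1.0 - maf_lpa)
    raw_var = float(np.sum(b_raw ** 2 * het_lpa))
    if cfg.lpa_log_genetic_var > 0 and raw_var > 0:
        b_lpa = b_raw * math.sqrt(cfg.lpa_log_genetic_var / raw_var)
    else:
        b_lpa = np.zeros(m1)

    # near-uniform magnitudes keep every LDL variant solidly detectable at
    # the genome-wide threshold (negligible winner's curse on the weights)
    d_raw = rng.lognormal(0.0, 0.3, m2) * rng.choice([-1.0, 1.0], m2)
    het_ldl = 2.0 * maf_ldl * (1.0 - maf_ldl)
    raw_var = float(np.sum(d_raw ** 2 * het_ldl))
    if cfg.ldl_genetic_sd > 0 and raw_var > 0:
        d_ldl = d_raw * math.sqrt(cfg.ldl_genetic_sd ** 2 / raw_var)
    else:
        d_ldl = np.zeros(m2)

    # --- covariates ------------------------------------------------------
    age = rng.normal(57.0, 8.0, n)
    sex = (rng.random(n) < 0.456).astype(float)  # 1 = male
    bmi = rng.normal(27.3, 4.5, n)
    sbp = rng.normal(138.0, 18.0, n)
    pcs = rng.standard_normal((n, 5))
    cov = {"age": age - 57.0, "sex": sex - 0.456, "bmi": bmi - 27.3,
           "sbp": sbp - 138.0}
    for k in range(5):
        cov[f"pc{k + 1}"] = pcs[:, k]

    # --- latent particle concentrations ---------------------------------
    ns = cfg.noise_sds
    log_lpa = (cfg.lpa_log_median
               + (g_lpa - 2.0 * maf_lpa) @ b_lpa
               + rng.normal(0.0, ns["lpa_log"], n))
    lpa_particles = np.exp(log_lpa)

    ldl_shift = np.zeros(n)
    for name, eff in cfg.covariate_lipid_effects.items():
        ldl_shift += eff * cov[name]
    ldl_particles = (cfg.baseline_particles["ldl"]
                     + (g_ldl - 2.0 * maf_ldl) @ d_ldl
                     + ldl_shift
                     + rng.normal(0.0, ns["ldl_particle"], n))
    ldl_particles = np.maximum(ldl_particles, 1.0)

    vldl_particles = np.maximum(
        rng.normal(cfg.baseline_particles["vldl"], ns["vldl_particle"], n), 1.0
    )

    apob_latent = lpa_particles + ldl_particles + vldl_particles  # exact

    # --- CHD outcome: logistic combined endpoint, one latent risk --------
    eta = (cfg.true_log_or_per_nmol_lpa * (lpa_particles - lpa_particles.mean())
           + cfg.true_log_or_per_nmol_ldl * (ldl_particles - ldl_particles.mean()))
    for name, eff in cfg.covariate_risk_effects.items():
        eta += eff * cov[name]
    p_case = expit(cfg.chd_logit_intercept + eta)
    case = rng.random(n) < p_case
    prevalent = case & (rng.random(n) < cfg.prevalent_fraction_of_cases)
    incident = case & ~prevalent

    followup = rng.uniform(cfg.followup_years - 2.0, cfg.followup_years + 2.0, n)
    # incident event times: exponential with subject-specific rate, thinned
    # (conditioned) to fall inside the realised follow-up window
    lam = cfg.incident_baseline_hazard * np.exp(eta)
    u = rng.random(n)
    with np.errstate(over="ignore"):
        t_event = -np.log1p(-u * (1.0 - np.exp(-lam * followup))) / np.maximum(lam, 1e-300)
    followup_time = np.where(incident, np.minimum(t_event, followup), followup)
    followup_time = np.where(prevalent, 0.0, followup_time)

    # --- measured phenotypes --------------------------------------------
    treated = rng.random(n) < cfg.treated_fraction
    mult = np.where(treated, cfg.treatment_ldl_multiplier, 1.0)

    lpa_mass = apply_assay_censoring(lpa_particles, *cfg.assay_range)
    apob_molar = (apob_latent + rng.normal(0.0, ns["apob"], n)) * mult
    apob_molar = np.maximum(apob_molar, 1.0)
    apob_mass = convert_apob_molar_to_mass(apob_molar)

    ldl_c = (ldl_particles * cfg.chol_per_ldl_particle
             + rng.normal(0.0, ns["ldl_c"], n)) * mult
    ldl_c = np.maximum(ldl_c, 0.1)
    remnant_c = np.maximum(
        vldl_particles * cfg.chol_per_vldl_particle + rng.normal(0.0, ns["remnant_c"], n),
        0.01,
    )
    hdl_c = np.maximum(rng.normal(cfg.hdl_c_mean, ns["hdl_c"], n), 0.4)
    total_c = ldl_c + hdl_c + remnant_c  # remnant identity holds by construction
    trig = np.maximum(
        vldl_particles * cfg.tg_per_vldl_particle + rng.normal(0.0, ns["triglycerides"], n),
        0.1,
    )

    # --- assemble --------------------------------------------------------
    subject_id = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    snp_ids = ([f"LPA_{j:04d}" for j in range(m1)]
               + [f"LDL_{j:04d}" for j in range(m2)]
               + [f"NULL_{j:04d}" for j in range(m0)])
    genotypes = pd.DataFrame(
        np.concatenate([g_lpa, g_ldl, g_null], axis=1),
        index=subject_id, columns=snp_ids,
    )
    snps = pd.DataFrame(
        {
            "effect_allele": "A",
            "other_allele": "G",
            "locus": ["LPA"] * m1 + ["LDL"] * m2 + ["NULL"] * m0,
            "maf": np.concatenate([maf_lpa, maf_ldl, maf_null]),
            "true_effect": np.concatenate([b_lpa, d_ldl, np.zeros(m0)]),
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    phenotypes = pd.DataFrame(
        {
            "lpa_mass": lpa_mass,
            "apob_mass": apob_mass,
            "total_c": total_c,
            "ldl_c": ldl_c,
            "hdl_c": hdl_c,
            "triglycerides": trig,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "sbp": sbp,
            **{f"pc{k + 1}": pcs[:, k] for k in range(5)},
            "on_lipid_lowering": treated.astype(int),
        },
        index=subject_id,
    )
    outcomes = pd.DataFrame(
        {
            "prevalent_chd": prevalent.astype(int),
            "incident_chd": incident.astype(int),
            "followup_years": followup_time,
        },
        index=subject_id,
    )

    manifest = {
        "config": asdict(cfg),
        "true_quotient": cfg.true_quotient,
        "true_log_or_per_nmol_lpa": cfg.true_log_or_per_nmol_lpa,
        "true_log_or_per_nmol_ldl": cfg.true_log_or_per_nmol_ldl,
        "lpa_locus_effects_log_scale": b_lpa.tolist(),
        "ldl_effects_nmol_per_allele": d_ldl.tolist(),
        "gwas_covariates": ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"],
        "n_prevalent": int(prevalent.sum()),
        "n_incident": int(incident.sum()),
        "n_treated": int(treated.sum()),
    }

    cohort = Cohort(genotypes, snps, phenotypes, outcomes, manifest).validate()
    cohort.latents = pd.DataFrame(
        {
            "lpa_particles": lpa_particles,
            "ldl_particles": ldl_particles,
            "vldl_particles": vldl_particles,
            "apob_particles": apob_latent,
            "risk_score": eta,
        },
        index=subject_id,
    )
    return cohort


def heldout_truth_check(cohort: Cohort, manifest: dict | None = None,
                        maf_tolerance: float = 0.02) -> dict:
    """Diagnostic report on structural invariants of a simulated cohort.

    Checks (pass/fail each, never raises):

    * ``apob_conservation`` — latent apoB equals the sum of the three
      particle species exactly (one apoB per particle);
    * ``lpa_right_skew`` — mean latent Lp(a) exceeds the median;
    * ``lpa_mass_identity`` — measured in-range Lp(a) mass equals the latent
      particle concentration one-to-one (regression slope 1);
    * ``maf_in_range`` — realised minor-allele frequencies fall within the
      configured range, widened by a binomial sampling tolerance.
    """
    manifest = manifest if manifest is not None else cohort.manifest
    lat = getattr(cohort, "latents", None)
    report = {}
    if lat is None:
        report["apob_conservation"] = {"passed": False, "detail": "no latent table"}
        report["lpa_right_skew"] = {"passed": False, "detail": "no latent table"}
        report["lpa_mass_identity"] = {"passed": False, "detail": "no latent table"}
    else:
        resid = np.abs(
            lat["apob_particles"]
            - (lat["lpa_particles"] + lat["ldl_particles"] + lat["vldl_particles"])
        ).max()
        report["apob_conservation"] = {"passed": bool(resid == 0.0), "max_residual": float(resid)}
        mean, median = float(lat["lpa_particles"].mean()), float(lat["lpa_particles"].median())
        report["lpa_right_skew"] = {"passed": bool(mean > median), "mean": mean, "median": median}
        mass = cohort.phenotypes["lpa_mass"].to_numpy()
        ok = ~np.isnan(mass)
        x = lat["lpa_particles"].to_numpy()[ok]
        slope = float(x @ mass[ok] / (x @ x)) if ok.any() else np.nan
        report["lpa_mass_identity"] = {
            "passed": bool(ok.any() and abs(slope - 1.0) < 1e-12),
            "slope": slope,
        }
    lo, hi = manifest["config"]["maf_range"] if manifest else (0.0, 0.5)
    dos = cohort.genotypes.to_numpy()
    freq = dos.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    n2 = 2.0 * cohort.n_subjects
    tol = max(maf_tolerance, 4.0 * math.sqrt(0.25 / n2))
    inside = (maf >= lo - tol) & (maf <= hi + tol)
    report["maf_in_range"] = {
        "passed": bool(inside.all()),
        "n_outside": int((~inside).sum()),
        "tolerance": tol,
    }
    report["all_passed"] = all(v["passed"] for k, v in report.items() if isinstance(v, dict))
    return report
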