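# Methods

## The question and the estimand

Lipoprotein(a) and LDL both carry exactly one apolipoprotein B-100 per
particle, so molar apoB (nmol/L) is a particle count and can serve as a
common exposure scale for the two species.  The pipeline estimates, for
each particle class, the CHD log odds ratio per nmol/L of apoB carried by
that class, reported as an odds ratio per a 50 nmol/L increment, and then
forms the **CHD risk quotient**

    q = theta_Lp(a) / theta_LDL,

the ratio of the two log odds ratios.  Because both are per the same apoB
increment, the increment cancels and q is the relative per-particle
atherogenicity of Lp(a) versus LDL.

## Analysis pipeline

1. **Per-SNP association scans** (`gwas`).  Quantitative lipid traits are
   analysed by exact least squares with covariate adjustment (age, sex,
   genomic PCs 1–5), computed by residualising trait and dosages on the
   covariate design — algebraically identical to the per-SNP joint fit.
   The combined prevalent+incident CHD endpoint is analysed by per-SNP
   logistic regression with the same covariates, fitted by IRLS batched
   across SNPs (convergence 1e-8 on the log-likelihood, iteration cap 40;
   separated fits are flagged and their SEs set missing).  Wald tests
   throughout.  Instrument-derivation scans use untreated subjects with
   the regressed trait available; CHD scans use all subjects.
2. **Selection and pruning**.  SNPs with p < 5e-8 and minor-allele
   frequency strictly above 0.01 are greedily clumped by ascending
   p-value: a SNP is kept only if its squared dosage correlation with
   every already-kept SNP is below 0.1 (ties broken on snp_id; stricter
   r² < 0.01 re-selection runs as a sensitivity analysis).
3. **Clusters** (`clusters`).  The Lp(a) cluster starts from the pruned
   Lp(a)-mass hits and removes variants genome-wide significant for
   LDL-C, remnant-C or triglycerides.  The LDL cluster starts from the
   pruned hits for triglycerides, remnant-C and/or LDL-C (joint pruning on
   the best p across the three), removes anything significant for Lp(a),
   anything with an unstable LDL-C beta (|beta| ≤ SE), and anything whose
   |beta_remnant-C| / |beta_LDL-C| ratio exceeds 0.15.  Every surviving
   variant is oriented to its apoB-raising allele and weighted by its
   apoB effect (nmol/L per allele).
4. **Mendelian randomisation** (`mr`).  Inverse-variance-weighted
   regression of per-SNP CHD log odds ratios on apoB betas is the primary
   estimator (exact zero-intercept WLS with weights 1/se²); MR-Egger and
   the weighted median are the pleiotropy-robust companions.  The design
   is one-sample (exposure betas from untreated subjects, outcome log ORs
   from all subjects), with a two-sample mode that accepts external CHD
   summary statistics and runs on the harmonised intersection.
5. **Polygenic scores** (`pgs`).  Each cluster yields a weighted
   apoB-raising allele count per subject; the cohort is split into
   ventiles of the score; incident CHD is analysed by a Cox
   proportional-hazards model on the continuous score (sex, BMI, age,
   systolic blood pressure as covariates; Breslow ties by default, Efron
   by flag; Newton iterations to 1e-9 relative log-likelihood with
   step-halving), and the log HR per score unit is rescaled through the
   least-squares slope of measured apoB on the score to an HR per
   50 nmol/L apoB.  Prevalent cases are excluded from the risk set.
6. **Risk quotient** (`quotient`).  Point estimate theta_Lp(a)/theta_LDL;
   95% CI by parametric bootstrap (independent normal draws of the two
   log ORs, percentile interval; the draws use the heterogeneity-inflated
   multiplicative random-effects SEs, whose point estimate is identical
   to the fixed-effect IVW).  A nonparametric SNP-resampling bootstrap is
   available for full-pipeline runs.  Replicates whose denominator draw
   crosses zero are counted; above 1% the interval is flagged unstable.

## The synthetic cohort

The generator produces individual-level data with the architecture the
analysis assumes, plus a ground-truth manifest:

* **LPA locus** — `n_lpa_locus_snps` (default 200) variants in LD,
  generated by Gaussian-copula thresholding of AR(1) haplotype chains
  (latent correlation 0.96) that restart every `lpa_locus_block_size`
  (default 10) variants.  The block structure mirrors haplotype blocks on
  real dense loci; r² < 0.1 clumping then keeps about one strong
  representative per block, so the surviving instruments are effectively
  independent — the assumption the IVW standard error relies on.
  Per-variant effects act on log Lp(a) (log-normal magnitudes, random
  sign, rescaled so the locus explains `lpa_log_genetic_var` = 0.25 of
  log-variance against a residual log-sd of 0.22, i.e. ~84% heritability).
  The marginal Lp(a) distribution is log-normal with median 36 nmol/L,
  mean ≈ 44 nmol/L and skewness ≈ 2 — strongly right-skewed, with a small
  (~0.2%) mass outside the 3.8–189 nmol/L assay range.
* **LDL variants** — independent, additive on the LDL particle
  concentration; near-uniform effect magnitudes (log-normal, sd 0.3 on the
  log) scaled so the variants jointly explain a 150 nmol/L particle-sd,
  which keeps every variant solidly detectable at 5e-8 and the selection
  essentially curse-free.
* **Null variants** — no effect on anything.
* **Conservation** — latent molar apoB is exactly Lp(a) + LDL + VLDL
  particles (one apoB per particle), and measured Lp(a) mass (nmol/L)
  equals the latent particle concentration one-to-one before censoring.
* **Phenotypes** — LDL-C proportional to LDL particles, remnant-C and
  triglycerides proportional to VLDL particles, HDL-C independent;
  total-C is the exact sum, so the remnant identity holds on every row.
  Covariates (age, sex, BMI, SBP, PCs) carry small effects on lipids and
  risk so adjustment is non-trivial.
* **Outcome** — one latent risk score, log-linear in the Lp(a) and LDL
  particle concentrations with per-particle log odds 0.005 and 0.005/6.6
  (ground-truth quotient 6.6, matching a 1.28-vs-1.04 OR pair per
  50 nmol/L).  The combined prevalent+incident endpoint is Bernoulli in
  that logit (~11% at baseline covariates); cases split 45% prevalent,
  and incident cases receive exponential event times conditioned into a
  10–14-year follow-up window.
* **Treatment** — a lipid-lowering flag (17% of subjects) multiplies
  *measured* LDL-C and apoB by 0.7 while latent values are untouched, so
  deriving instruments from untreated subjects removes the bias — which
  makes the exclusion rule testable.

### Why the defaults are not the real cohort's marginals

Two experiments during design fixed the defaults:

* With the real-world Lp(a) marginal (median ≈ 21, mean ≈ 45, ~16% of
  mass outside the assay range), the natural-scale tail is so heavy that
  (a) a logistic risk model that is log-linear in particles saturates for
  the top percentile and per-SNP outcome log ORs no longer scale as
  theta × beta_exposure (≈ +20% distortion of theta_Lp(a)), and (b) the
  in-range subsample's natural-scale betas attenuate by up to ~50%, which
  destroys either quotient recovery or the unity diagnostic depending on
  which sample the apoB scan uses.  Neither artefact is a bug — both are
  real properties of the design assumptions pushed outside their linear
  regime — but a generator whose ground truth cannot be recovered by the
  method it is meant to validate is useless as a test bed.
* Instrument strength: recovery of theta within ~5% needs the summed
  squared apoB betas of the selected instruments to dominate the summed
  squared sampling errors (the errors-in-variables budget).  The defaults
  were chosen by this power analysis — moderate skew, high heritability,
  LD blocks that collapse to ~20 strong independent instruments — and
  then frozen before the test suite was written.

The generator therefore reproduces the *qualitative* features the
analysis relies on (right-skew, assay censoring, one-apoB-per-particle,
LD, treatment perturbation, shared prevalent/incident risk), not the UK
population's exact numbers; all of its parameters are exposed in
`SimulationConfig` for anyone who wants to explore harsher regimes.

### What passing tests do and do not show

Passing recovery tests show the estimator chain is consistent under its
own assumptions at realistic effect sizes and cohort scale.  They do not
show that real Lp(a) data satisfy those assumptions: real assays have
isoform-dependent bias, real LDL-C indices include Lp(a) cholesterol,
real loci have allelic series and kringle-repeat structure none of which
is modelled, and the log-linear risk model is itself an approximation
whose failure at extreme Lp(a) the experiments above quantify.

## The agreement diagnostic

The structural check that genetically predicted Lp(a)-apoB is mole-for-
mole with Lp(a) mass regresses per-SNP Lp(a)-mass betas on apoB betas
(naive OLS through the origin) over the Lp(a) cluster.  Two choices make
this test the identity rather than an artefact:

* both scans run on the **matched** untreated complete-panel sample, so
  the assay-range truncation attenuates the two coordinates identically
  and cancels in the slope;
* the apoB scan additionally adjusts for LDL-C and triglycerides.  For
  LPA-locus variants these covariates are independent of dosage, so the
  betas are unbiased, but the adjustment removes the large non-Lp(a)
  share of apoB variance from the residual and with it most of the
  errors-in-variables dilution of the slope.

MR weights deliberately do **not** use these adjusted betas: the exposure
of interest there is total apoB under the standard age/sex/PC adjustment.

## Problem sizes

Default single-cohort analyses run at n = 50,000 subjects with 200 + 150
+ 500 variants.  Replicate studies (parameter recovery, null calibration)
run at half scale — n = 25,000 with variant counts halved and per-particle
effects unchanged — which preserves per-instrument z-scores and the
errors-in-variables budget exactly, with 150 (recovery) and 60 (null)
replicates.  Half-scale behaviour measured during design: mean quotient
within ~2–5% of truth, CI coverage ≈ 0.92–0.95, agreement slope
0.99 ± 0.03.

## Numerical conventions

* All particle computations in nmol/L; conversions (2.2 nmol/L per mg/dL
  for Lp(a) — an assay-calibration approximation exposed as a constant,
  not asserted as physical truth — and 550 kDa for apoB) only at I/O
  boundaries.
* Missing values are empty TSV fields / NaN, never sentinels; assay
  censoring maps out-of-range Lp(a) to missing.
* Doubles end to end; significant-figure rounding only in the report
  layer (ORs at two decimals, quotients at one).
* Greedy pruning ties break lexicographically on snp_id; all randomness
  flows from explicit integer seeds (simulation, bootstrap, weighted-
  median resampling), making every pipeline run bit-reproducible.
* Logistic IRLS warm-starts at the covariate-only fit; the Cox Newton
  solver centres covariates and step-halves; both have fixed iteration
  caps and raise (Cox) or flag (logistic) on failure.

## Known limitations

* One-sample overlap between exposure and outcome samples is accepted, as
  in the design being emulated; no winner's-curse or NOME correction is
  applied (the generator is calibrated so these are small, not absent).
* The weighted-median SE is a parametric bootstrap holding exposure betas
  fixed (first-order); Egger SEs carry the usual dispersion floor.
* The parametric quotient CI assumes the two clusters' estimates are
  independent (disjoint SNP sets, shared subjects ignored).
* No fine-mapping, relatedness correction, genomic control, X chromosome,
  competing risks or time-varying covariates.
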