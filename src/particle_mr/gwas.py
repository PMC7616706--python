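"""Per-SNP association scans with covariate adjustment, and LD pruning.

Quantitative traits are analysed by exact per-SNP least squares with
covariates, computed by residualising both trait and dosages on the
covariate design (Frisch-Waugh) — algebraically identical to fitting the
joint model per SNP, but one matrix factorisation serves every SNP.  The
binary CHD endpoint (prevalent or incident) is analysed by per-SNP logistic
regression, fitted by iteratively reweighted least squares batched across
SNPs.  Wald tests throughout.

Instrument-derivation convention: quantitative-trait scans default to
subjects not on lipid-lowering therapy with the regressed trait available
(``untreated_with_lipids``); the CHD scan defaults to all subjects.

:func:`filter_and_prune` applies the genome-wide significance and
minor-allele-frequency filters and then greedy p-ordered LD clumping:
survivors are visited in order of ascending p-value and accepted only if
their squared dosage correlation with every already-accepted SNP stays
below the threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

QUANTITATIVE_TRAITS = ("lpa_mass", "apob_molar", "ldl_c", "remnant_c", "triglycerides")
DEFAULT_GWAS_COVARIATES = ("age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5")

#: Genome-wide selection defaults.
P_THRESHOLD = 5e-8
MAF_THRESHOLD = 0.01
R2_THRESHOLD = 0.1

_IRLS_TOL = 1e-8       # convergence tolerance on the per-SNP log-likelihood
_IRLS_MAX_ITER = 40
_SEPARATION_BETA = 25.0  # |log OR| beyond which a fit is treated as separated


#: lipid panel that must be complete for instrument derivation
_REQUIRED_PANEL = ("lpa_mass", "apob_mass", "total_c", "ldl_c", "hdl_c",
                   "triglycerides")


def _analysis_rows(cohort, trait: str, covariates, subject_filter: str) -> np.ndarray:
    ph = cohort.phenotypes
    ok = np.ones(cohort.n_subjects, dtype=bool)
    for c in covariates:
        ok &= ~pd.isna(ph[c].to_numpy(dtype=float))
    if subject_filter == "untreated_with_lipids":
        # instrument derivation: untreated subjects with the regressed
        # trait available
        ok &= ph["on_lipid_lowering"].to_numpy() == 0
        if trait != "chd":
            ok &= ~pd.isna(ph[trait].to_numpy(dtype=float))
    elif subject_filter == "untreated_complete_panel":
        # matched sample across traits: untreated subjects with the FULL
        # lipid panel available (incl. in-range Lp(a)).  Used for the
        # beta-beta agreement diagnostic so that assay-range truncation
        # attenuates the betas of both traits identically.
        ok &= ph["on_lipid_lowering"].to_numpy() == 0
        for col in _REQUIRED_PANEL:
            ok &= ~pd.isna(ph[col].to_numpy(dtype=float))
    elif subject_filter == "all":
        if trait != "chd":
            ok &= ~pd.isna(ph[trait].to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown subject_filter {subject_filter!r}")
    return ok


def _covariate_design(cohort, covariates, rows: np.ndarray) -> np.ndarray:
    cols = [np.ones(int(rows.sum()))]
    for c in covariates:
        cols.append(cohort.phenotypes[c].to_numpy(dtype=float)[rows])
    return np.column_stack(cols)


def _linear_scan(y, G, C):
    """Exact per-SNP OLS of y on dosage + covariates via residualisation."""
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", G_r, G_r)
    degenerate = gg <= 1e-10 * G.shape[0]
    gg_safe = np.where(degenerate, 1.0, gg)
    gy = G_r.T @ y_r
    beta = gy / gg_safe
    df = G.shape[0] - C.shape[1] - 1
    ssr = np.maximum(y_r @ y_r - beta * gy, 0.0)
    sigma2 = ssr / df
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    pval[degenerate] = np.nan
    return beta, se, pval, degenerate


def _logistic_null_fit(y, C):
    """Covariate-only logistic fit (plain IRLS) used to warm-start the scan."""
    beta = np.zeros(C.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-12) / max(1.0 - y.mean(), 1e-12))
    ll_old = -np.inf
    for _ in range(_IRLS_MAX_ITER):
        eta = C @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = C.T @ (y - mu)
        H = (C * w[:, None]).T @ C
        beta = beta + np.linalg.solve(H, grad)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if abs(ll - ll_old) < _IRLS_TOL * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    return beta


def _logistic_scan(y, G, C, chunk: int = 256):
    """Per-SNP logistic regression batched over SNPs (shared covariates).

    Returns beta, se, p per SNP; separated or non-converged fits keep the
    last coefficient but have SE and p set missing.
    """
    n, k = C.shape
    S = G.shape[1]
    beta_g = np.full(S, np.nan)
    se_g = np.full(S, np.nan)
    flagged = np.zeros(S, dtype=bool)
    warm = _logistic_null_fit(y, C)
    iu = np.triu_indices(k)
    P = C[:, iu[0]] * C[:, iu[1]]  # n x k(k+1)/2 products for Hessian blocks

    for start in range(0, S, chunk):
        Gc = G[:, start:start + chunk]
        s = Gc.shape[1]
        bc = np.tile(warm, (s, 1))            # (s, k)
        bg = np.zeros(s)
        ll_old = np.full(s, -np.inf)
        active = np.ones(s, dtype=bool)
        for _ in range(_IRLS_MAX_ITER):
            eta = C @ bc.T + Gc * bg          # (n, s)
            mu = expit(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-12)
            resid = y[:, None] - mu
            grad_c = C.T @ resid              # (k, s)
            grad_g = np.einsum("ns,ns->s", Gc, resid)
            Hcc = P.T @ w                     # (npairs, s)
            Hcg = C.T @ (Gc * w)              # (k, s)
            Hgg = np.einsum("ns,ns->s", Gc * Gc, w)
            H = np.zeros((s, k + 1, k + 1))
            H[:, iu[0], iu[1]] = Hcc.T
            H[:, iu[1], iu[0]] = Hcc.T
            H[:, :k, k] = Hcg.T
            H[:, k, :k] = Hcg.T
            H[:, k, k] = Hgg
            g_full = np.concatenate([grad_c, grad_g[None, :]], axis=0).T  # (s, k+1)
            try:
                step = np.linalg.solve(H, g_full[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.array([np.linalg.lstsq(H[i], g_full[i], rcond=None)[0]
                                 for i in range(s)])
            step = np.where(active[:, None], step, 0.0)
            bc += step[:, :k]
            bg += step[:, k]
            ll = np.einsum("n,ns->s", y, eta) - np.logaddexp(0.0, eta).sum(axis=0)
            active = np.abs(ll - ll_old) >= _IRLS_TOL * (np.abs(ll_old) + 1.0)
            ll_old = ll
            if not active.any():
                break
        converged = ~active
        bad = (~np.isfinite(bg)) | (np.abs(bg) > _SEPARATION_BETA) | ~converged
        # SEs from the inverse observed information at the final iterate
        eta = C @ bc.T + Gc * bg
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        Hcc = P.T @ w
        Hcg = C.T @ (Gc * w)
        Hgg = np.einsum("ns,ns->s", Gc * Gc, w)
        H = np.zeros((s, k + 1, k + 1))
        H[:, iu[0], iu[1]] = Hcc.T
        H[:, iu[1], iu[0]] = Hcc.T
        H[:, :k, k] = Hcg.T
        H[:, k, :k] = Hcg.T
        H[:, k, k] = Hgg
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.inv(H)
                se = np.sqrt(cov[:, k, k])
            except np.linalg.LinAlgError:
                se = np.full(s, np.nan)
                bad[:] = True
        beta_g[start:start + s] = bg
        se_g[start:start + s] = np.where(bad, np.nan, se)
        flagged[start:start + s] = bad
    with np.errstate(invalid="ignore"):
        z = beta_g / se_g
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return beta_g, se_g, pval, flagged


def associate(cohort, trait: str,
              covariates=DEFAULT_GWAS_COVARIATES,
              subject_filter: str | None = None,
              snp_ids=None) -> pd.DataFrame:
    """Per-SNP association scan for one trait.

    Parameters
    ----------
    cohort : Cohort
    trait : str
        One of the quantitative traits (``lpa_mass``, ``apob_molar``,
        ``ldl_c``, ``remnant_c``, ``triglycerides``) or ``chd`` (the
        combined prevalent+incident endpoint, logistic model).
    covariates : sequence of phenotype column names
    subject_filter : {"untreated_with_lipids", "all"} or None
        Defaults to ``untreated_with_lipids`` for quantitative traits and
        ``all`` for ``chd``.
    snp_ids : optional subset of SNPs to scan.

    Returns
    -------
    DataFrame in summary-statistics layout (snp_id, effect_allele,
    other_allele, eaf, beta, se, pvalue, n, trait).  Betas are in trait
    units per effect allele; log odds per allele for ``chd``.
    """
    if trait != "chd" and trait not in QUANTITATIVE_TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    if subject_filter is None:
        subject_filter = "all" if trait == "chd" else "untreated_with_lipids"
    rows = _analysis_rows(cohort, trait, covariates, subject_filter)
    ids = list(cohort.genotypes.columns if snp_ids is None else snp_ids)
    G = cohort.dosage_matrix(ids)[rows]
    C = _covariate_design(cohort, covariates, rows)
    n_used = int(rows.sum())

    if trait == "chd":
        y = ((cohort.outcomes["prevalent_chd"].to_numpy() == 1)
             | (cohort.outcomes["incident_chd"].to_numpy() == 1)).astype(float)[rows]
        sd = G.std(axis=0)
        degenerate = sd == 0.0
        beta = np.full(len(ids), np.nan)
        se = np.full(len(ids), np.nan)
        pval = np.full(len(ids), np.nan)
        if (~degenerate).any():
            b, s, p, bad = _logistic_scan(y, G[:, ~degenerate], C)
            beta[~degenerate], se[~degenerate], pval[~degenerate] = b, s, p
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} logistic fit(s) flagged "
                    "(separation or non-convergence); SE set missing"
                )
    else:
        y = cohort.phenotypes[trait].to_numpy(dtype=float)[rows]
        beta, se, pval, degenerate = _linear_scan(y, G, C)
    if degenerate.any():
        skipped = [ids[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"skipped {len(skipped)} constant/collinear dosage column(s): "
                      f"{skipped[:5]}")

    meta = cohort.snps.loc[ids]
    out = pd.DataFrame(
        {
            "snp_id": ids,
            "effect_allele": meta["effect_allele"].to_numpy(),
            "other_allele": meta["other_allele"].to_numpy(),
            "eaf": G.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "n": n_used,
            "trait": trait,
        }
    )
    keep = ~np.asarray(degenerate)
    return out.loc[keep].reset_index(drop=True)


def filter_and_prune(associations: pd.DataFrame, dosages: pd.DataFrame,
                     p_threshold: float = P_THRESHOLD,
                     maf_threshold: float = MAF_THRESHOLD,
                     r2_threshold: float = R2_THRESHOLD) -> list[str]:
    """Significance + MAF filter followed by greedy p-ordered LD clumping.

    Keeps SNPs with ``pvalue < p_threshold`` and folded MAF strictly above
    ``maf_threshold`` (MAF computed from the dosage mean), then visits
    survivors by ascending p-value (ties broken on snp_id) and accepts a SNP
    only if its squared Pearson dosage correlation with every
    already-accepted SNP is below ``r2_threshold``.  Returns accepted
    snp_ids; an empty survivor set returns an empty list.
    """
    assoc = associations.dropna(subset=["pvalue"])
    missing = set(assoc["snp_id"]) - set(dosages.columns)
    if missing:
        raise ValueError(f"dosages missing for SNPs: {sorted(missing)[:5]!r}")
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = assoc.loc[
        (assoc["pvalue"] < p_threshold)
        & (assoc["snp_id"].map(maf) > maf_threshold)
    ]
    if keep.empty:
        return []
    order = keep.sort_values(["pvalue", "snp_id"], kind="mergesort")["snp_id"].tolist()
    X = dosages[order].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", X, X))
    norms[norms == 0.0] = 1.0
    X = X / norms
    accepted_idx: list[int] = []
    for j in range(len(order)):
        if accepted_idx:
            r = X[:, accepted_idx].T @ X[:, j]
            if np.max(r * r) >= r2_threshold:
                continue
        accepted_idx.append(j)
    return [order[j] for j in accepted_idx]
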