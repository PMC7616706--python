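"""Construction of the 'Lp(a)' and 'LDL' SNP clusters.

The Lp(a) cluster starts from the LD-pruned genome-wide-significant hits for
Lp(a) mass concentration and drops variants with significant effects on the
other lipid fractions (LDL-C, remnant-C, triglycerides) — pleiotropy that
would contaminate a particle-specific instrument.  The LDL cluster starts
from the pruned hits for triglycerides, remnant-C and/or LDL-C, drops
anything significant for Lp(a), and additionally drops variants whose
remnant-C : LDL-C effect-size ratio exceeds a cap (default 0.15), so that
remnant particles contribute as little as possible to the genetically
predicted LDL-C signal.

Every surviving SNP is oriented to its apoB-raising allele and carries its
apoB (nmol/L per allele) effect as weight; the provenance table accounts for
every candidate SNP and the rule that removed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import filter_and_prune, P_THRESHOLD, MAF_THRESHOLD, R2_THRESHOLD


class ClusterError(RuntimeError):
    """Empty cluster or inconsistent association inputs."""


@dataclass
class SnpCluster:
    """Named SNP set with apoB-raising orientation and per-SNP apoB weights.

    ``table`` is indexed by snp_id with columns ``effect_allele``
    (apoB-raising), ``other_allele`` and ``apob_weight`` (nmol/L per raising
    allele, >= 0).  ``provenance`` has one row per candidate SNP with the
    rule that removed it ('retained' for members).
    """

    name: str
    table: pd.DataFrame
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def snp_ids(self) -> list:
        return list(self.table.index)

    @property
    def apob_weights(self) -> np.ndarray:
        return self.table["apob_weight"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index().rename(columns={"index": "snp_id"})


def _indexed(assoc: pd.DataFrame) -> pd.DataFrame:
    df = assoc.set_index("snp_id")
    if df.index.duplicated().any():
        raise ClusterError("duplicated snp_id within an association set")
    return df


def _orient_to_apob_raising(snp_ids, assoc_apob: pd.DataFrame) -> pd.DataFrame:
    """Flip alleles so the effect allele raises apoB; weights become >= 0."""
    apob = _indexed(assoc_apob)
    missing = [s for s in snp_ids if s not in apob.index]
    if missing:
        raise ClusterError(f"no apoB association for SNPs {missing[:5]!r}")
    rows = []
    for s in snp_ids:
        beta = float(apob.at[s, "beta"])
        ea, oa = apob.at[s, "effect_allele"], apob.at[s, "other_allele"]
        if beta < 0:
            ea, oa, beta = oa, ea, -beta
        rows.append({"snp_id": s, "effect_allele": ea, "other_allele": oa,
                     "apob_weight": beta})
    return pd.DataFrame(rows).set_index("snp_id")


def _prune_provenance(assoc, dosages, p_threshold, maf_threshold, r2_threshold):
    """Run filter_and_prune and classify every input SNP."""
    survivors = filter_and_prune(assoc, dosages, p_threshold, maf_threshold,
                                 r2_threshold)
    surv = set(survivors)
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    rules = {}
    for _, row in assoc.iterrows():
        s = row["snp_id"]
        if s in surv:
            rules[s] = "retained"
        elif not np.isfinite(row["pvalue"]) or row["pvalue"] >= p_threshold:
            rules[s] = "not_significant"
        elif maf.get(s, 0.0) <= maf_threshold:
            rules[s] = "low_maf"
        else:
            rules[s] = "ld_pruned"
    return survivors, rules


def build_lpa_cluster(assoc_by_trait: dict, dosages: pd.DataFrame,
                      p_threshold: float = P_THRESHOLD,
                      maf_threshold: float = MAF_THRESHOLD,
                      r2_threshold: float = R2_THRESHOLD,
                      pleiotropy_p: float = P_THRESHOLD) -> SnpCluster:
    """Build the Lp(a) cluster.

    Needs association sets for ``lpa_mass``, ``ldl_c``, ``remnant_c``,
    ``triglycerides`` and ``apob_molar`` on a common SNP universe, plus the
    dosage matrix for LD pruning.
    """
    for t in ("lpa_mass", "ldl_c", "remnant_c", "triglycerides", "apob_molar"):
        if t not in assoc_by_trait:
            raise ClusterError(f"missing association set for trait {t!r}")
    survivors, rules = _prune_provenance(
        assoc_by_trait["lpa_mass"], dosages, p_threshold, maf_threshold, r2_threshold
    )
    other = {t: _indexed(assoc_by_trait[t]) for t in ("ldl_c", "remnant_c", "triglycerides")}
    kept = []
    for s in survivors:
        hit = None
        for t, df in other.items():
            if s in df.index and np.isfinite(df.at[s, "pvalue"]) \
                    and df.at[s, "pvalue"] < pleiotropy_p:
                hit = t
                break
        if hit is not None:
            rules[s] = f"pleiotropy_{hit}"
        else:
            kept.append(s)
    provenance = pd.DataFrame(
        {"snp_id": list(rules), "rule": [rules[s] for s in rules]}
    )
    if not kept:
        raise ClusterError(
            f"Lp(a) cluster is empty; provenance:\n{provenance.to_string(index=False)}"
        )
    table = _orient_to_apob_raising(kept, assoc_by_trait["apob_molar"])
    return SnpCluster("Lp(a)", table, provenance)


def build_ldl_cluster(assoc_by_trait: dict, dosages: pd.DataFrame,
                      p_threshold: float = P_THRESHOLD,
                      maf_threshold: float = MAF_THRESHOLD,
                      r2_threshold: float = R2_THRESHOLD,
                      pleiotropy_p: float = P_THRESHOLD,
                      remnant_ratio_max: float = 0.15) -> SnpCluster:
    """Build the LDL cluster.

    Candidates are SNPs genome-wide significant for triglycerides,
    remnant-C and/or LDL-C (pruned jointly on the best p-value across the
    three traits); SNPs significant for Lp(a) mass are excluded, as are
    SNPs with an unstable LDL-C beta (|beta| <= SE) or a
    remnant-C : LDL-C absolute effect-size ratio above ``remnant_ratio_max``.
    """
    for t in ("lpa_mass", "ldl_c", "remnant_c", "triglycerides", "apob_molar"):
        if t not in assoc_by_trait:
            raise ClusterError(f"missing association set for trait {t!r}")
    lipid = {t: _indexed(assoc_by_trait[t]) for t in ("triglycerides", "remnant_c", "ldl_c")}
    universe = sorted(set().union(*(df.index for df in lipid.values())))
    min_p = pd.DataFrame(
        {
            "snp_id": universe,
            "pvalue": [
                np.nanmin([df.at[s, "pvalue"] if s in df.index else np.nan
                           for df in lipid.values()])
                for s in universe
            ],
        }
    )
    survivors, rules = _prune_provenance(
        min_p, dosages[universe], p_threshold, maf_threshold, r2_threshold
    )
    lpa = _indexed(assoc_by_trait["lpa_mass"])
    ldl = lipid["ldl_c"]
    rem = lipid["remnant_c"]
    kept = []
    for s in survivors:
        if s in lpa.index and np.isfinite(lpa.at[s, "pvalue"]) \
                and lpa.at[s, "pvalue"] < pleiotropy_p:
            rules[s] = "lpa_significant"
            continue
        b_ldl = float(ldl.at[s, "beta"]) if s in ldl.index else np.nan
        se_ldl = float(ldl.at[s, "se"]) if s in ldl.index else np.nan
        if not np.isfinite(b_ldl) or abs(b_ldl) <= se_ldl or b_ldl == 0.0:
            rules[s] = "unstable_ldl_beta"
            continue
        b_rem = float(rem.at[s, "beta"]) if s in rem.index else 0.0
        if abs(b_rem) / abs(b_ldl) > remnant_ratio_max:
            rules[s] = "remnant_ratio"
            continue
        kept.append(s)
    provenance = pd.DataFrame(
        {"snp_id": list(rules), "rule": [rules[s] for s in rules]}
    )
    if not kept:
        raise ClusterError(
            f"LDL cluster is empty; provenance:\n{provenance.to_string(index=False)}"
        )
    table = _orient_to_apob_raising(kept, assoc_by_trait["apob_molar"])
    return SnpCluster("LDL", table, provenance)


def harmonise_to_cluster(cluster: SnpCluster, assoc: pd.DataFrame,
                         require_all: bool = True) -> pd.DataFrame:
    """Align an association set to the cluster's apoB-raising orientation.

    Returns a DataFrame indexed by snp_id (cluster order, intersected with
    the association set) with ``beta`` flipped wherever the association's
    effect allele is the cluster's other allele.  Raises on allele pairs
    that cannot be reconciled, listing the offending SNPs.
    """
    df = _indexed(assoc)
    present = [s for s in cluster.snp_ids if s in df.index]
    if require_all and len(present) != len(cluster):
        missing = sorted(set(cluster.snp_ids) - set(present))
        raise ClusterError(f"association set missing cluster SNPs {missing[:5]!r}")
    bad, rows = [], []
    for s in present:
        ea_c = cluster.table.at[s, "effect_allele"]
        oa_c = cluster.table.at[s, "other_allele"]
        ea, oa = df.at[s, "effect_allele"], df.at[s, "other_allele"]
        rec = df.loc[s].copy()
        if (ea, oa) == (ea_c, oa_c):
            pass
        elif (ea, oa) == (oa_c, ea_c):
            rec["beta"] = -rec["beta"]
            rec["effect_allele"], rec["other_allele"] = ea_c, oa_c
            if "eaf" in rec:
                rec["eaf"] = 1.0 - rec["eaf"]
        else:
            bad.append(s)
            continue
        rows.append(rec.rename(s))
    if bad:
        raise ClusterError(f"allele orientation mismatch for SNPs {bad[:10]!r}")
    return pd.DataFrame(rows)


def beta_beta_diagnostic(cluster: SnpCluster, assoc_lpa: pd.DataFrame,
                         assoc_apob: pd.DataFrame) -> dict | None:
    """Agreement of per-SNP Lp(a)-mass and apoB betas (both nmol/L).

    Ordinary least squares through the origin of the Lp(a)-mass betas on the
    apoB betas over the cluster SNPs, both oriented to the cluster's
    apoB-raising alleles.  One mole of Lp(a)-apoB is one mole of Lp(a), so
    for a genuine Lp(a) cluster the slope should sit near unity.

    Returns ``{"slope", "se", "n_snps", "pairs"}``; with fewer than three
    cluster SNPs the diagnostic is skipped (returns None with a warning).
    """
    if len(cluster) < 3:
        warnings.warn("fewer than 3 SNPs in cluster; beta-beta diagnostic skipped")
        return None
    lpa = harmonise_to_cluster(cluster, assoc_lpa, require_all=False)
    apob = harmonise_to_cluster(cluster, assoc_apob, require_all=False)
    common = [s for s in cluster.snp_ids if s in lpa.index and s in apob.index]
    x = apob.loc[common, "beta"].to_numpy(dtype=float)
    y = lpa.loc[common, "beta"].to_numpy(dtype=float)
    sxx = float(x @ x)
    if sxx == 0.0:
        warnings.warn("all apoB betas zero; beta-beta diagnostic skipped")
        return None
    slope = float(x @ y) / sxx
    resid = y - slope * x
    dof = max(len(common) - 1, 1)
    se = float(np.sqrt((resid @ resid) / dof / sxx))
    pairs = pd.DataFrame({"snp_id": common, "beta_apob": x, "beta_lpa_mass": y})
    return {"slope": slope, "se": se, "n_snps": len(common), "pairs": pairs}
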