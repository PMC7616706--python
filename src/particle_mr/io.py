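"""Cohort and summary-statistic readers and writers.

A cohort is three aligned tab-delimited tables (plus optional SNP metadata):
genotype dosages (subjects x SNPs, effect-allele counts in [0, 2], imputed
non-integers allowed), a phenotype table (lipid panel, covariates, genomic
PCs, lipid-lowering-therapy flag) and an outcome table (prevalent CHD flag,
incident CHD flag, follow-up years).  Genotypes may alternatively come from
a VCF (DS format field preferred, GT fallback).  Missing values are empty
TSV fields, surfaced as NaN — never 0 or a sentinel.

Summary statistics are one row per SNP x trait with columns
``snp_id, effect_allele, other_allele, eaf, beta, se, pvalue, n, trait``
and round-trip losslessly through :func:`write_summary_stats` /
:func:`read_summary_stats`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import convert_apob_mass_to_molar, derive_remnant_c

SUMMARY_STAT_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "trait",
]

#: Mandated phenotype columns (units in docs/data_dictionary.md).
PHENOTYPE_COLUMNS = [
    "lpa_mass",       # nmol/L, assay-censored, may be missing
    "apob_mass",      # g/L
    "total_c",        # mmol/L
    "ldl_c",          # mmol/L
    "hdl_c",          # mmol/L
    "triglycerides",  # mmol/L
    "age",            # years
    "sex",            # 1 = male, 0 = female
    "bmi",            # kg/m^2
    "sbp",            # mmHg
    "pc1", "pc2", "pc3", "pc4", "pc5",
    "on_lipid_lowering",  # 0/1
]

OUTCOME_COLUMNS = ["prevalent_chd", "incident_chd", "followup_years"]


class CohortParseError(ValueError):
    """Malformed or inconsistent cohort input files."""


@dataclass
class Cohort:
    """Individual-level cohort: genotypes, phenotypes and CHD outcomes.

    Attributes
    ----------
    genotypes : DataFrame, subjects x SNPs
        Effect-allele dosages in [0, 2].
    snps : DataFrame indexed by snp_id
        Columns ``effect_allele, other_allele`` and optionally
        ``locus`` (LPA / LDL / NULL in simulated cohorts) and ``maf``.
    phenotypes : DataFrame indexed by subject_id
        Lipid panel and covariates; derived columns ``remnant_c`` (mmol/L)
        and ``apob_molar`` (nmol/L) are always present.
    outcomes : DataFrame indexed by subject_id
    """

    genotypes: pd.DataFrame
    snps: pd.DataFrame
    phenotypes: pd.DataFrame
    outcomes: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> "Cohort":
        """Check alignment and invariants; derive remnant_c / apob_molar."""
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise CohortParseError(
                "subject identifiers differ between genotype and phenotype tables"
            )
        if not self.genotypes.index.equals(self.outcomes.index):
            raise CohortParseError(
                "subject identifiers differ between genotype and outcome tables"
            )
        if self.genotypes.columns.duplicated().any():
            dup = self.genotypes.columns[self.genotypes.columns.duplicated()][0]
            raise CohortParseError(f"duplicated snp_id {dup!r} in genotype table")
        dos = self.genotypes.to_numpy(dtype=float)
        bad = np.argwhere(~np.isnan(dos) & ((dos < 0) | (dos > 2)))
        if bad.size:
            i, j = bad[0]
            raise CohortParseError(
                f"dosage {dos[i, j]} outside [0, 2] for subject "
                f"{self.genotypes.index[i]!r}, SNP {self.genotypes.columns[j]!r}"
            )
        missing_snps = self.genotypes.columns.difference(self.snps.index)
        if len(missing_snps):
            raise CohortParseError(
                f"SNPs without metadata: {list(missing_snps[:5])!r}"
            )
        ph = self.phenotypes
        ph["remnant_c"] = derive_remnant_c(ph["total_c"], ph["ldl_c"], ph["hdl_c"])
        ph["apob_molar"] = convert_apob_mass_to_molar(ph["apob_mass"].to_numpy())
        for col in ["lpa_mass", "apob_mass", "total_c", "ldl_c", "hdl_c",
                    "triglycerides"]:
            vals = ph[col].to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] < 0):
                raise CohortParseError(f"negative concentration in column {col!r}")
        return self

    def dosage_matrix(self, snp_ids=None) -> np.ndarray:
        """Dosages as a float array (subjects x selected SNPs)."""
        g = self.genotypes if snp_ids is None else self.genotypes[list(snp_ids)]
        return g.to_numpy(dtype=float)


def _read_dosage_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "subject_id":
        raise CohortParseError(
            f"first column of dosage matrix must be 'subject_id', got {df.columns[0]!r}"
        )
    df = df.set_index("subject_id")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise CohortParseError(f"duplicated snp_id {dup!r} in dosage header")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise CohortParseError(f"non-numeric dosage value: {exc}") from exc


def _read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read dosages from a VCF; DS preferred, GT fallback (ALT = effect allele)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    dosages, meta = {}, []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in dosages:
            raise CohortParseError(f"duplicated snp_id {snp_id!r} in VCF")
        ds = None
        try:
            arr = var.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is None:
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1))
            ds = ds.astype(float)
        dosages[snp_id] = ds
        meta.append(
            {
                "snp_id": snp_id,
                "effect_allele": var.ALT[0] if var.ALT else ".",
                "other_allele": var.REF,
            }
        )
    geno = pd.DataFrame(dosages, index=pd.Index(subjects, name="subject_id"))
    snps = pd.DataFrame(meta).set_index("snp_id")
    return geno, snps


def read_cohort(genotype_path, phenotype_path, outcome_path,
                snp_metadata_path=None) -> Cohort:
    """Read and validate a cohort from disk.

    ``genotype_path`` may be a dosage TSV or a VCF (suffix ``.vcf`` /
    ``.vcf.gz``).  For TSV genotypes, allele metadata comes from
    ``snp_metadata_path`` when given (TSV: snp_id, effect_allele,
    other_allele, ...); otherwise placeholder alleles ``EA``/``OA`` are
    assigned.
    """
    for p in (genotype_path, phenotype_path, outcome_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    name = str(genotype_path)
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        geno, snps = _read_vcf(genotype_path)
    else:
        geno = _read_dosage_tsv(genotype_path)
        if snp_metadata_path is not None:
            snps = pd.read_csv(snp_metadata_path, sep="\t", dtype={"snp_id": str})
            snps = snps.set_index("snp_id")
        else:
            snps = pd.DataFrame(
                {"effect_allele": "EA", "other_allele": "OA"},
                index=geno.columns.rename("snp_id"),
            )
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"subject_id": str})
    pheno = pheno.set_index("subject_id")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise CohortParseError(f"phenotype table missing columns {missing!r}")
    outc = pd.read_csv(outcome_path, sep="\t", dtype={"subject_id": str})
    outc = outc.set_index("subject_id")
    missing = [c for c in OUTCOME_COLUMNS if c not in outc.columns]
    if missing:
        raise CohortParseError(f"outcome table missing columns {missing!r}")
    return Cohort(geno, snps, pheno, outc).validate()


def write_cohort(cohort: Cohort, out_dir, prefix: str = "cohort") -> dict:
    """Write a cohort as four TSVs (+ JSON manifest); returns the path map."""
    import json

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(out_dir, f"{prefix}.genotypes.tsv"),
        "snps": os.path.join(out_dir, f"{prefix}.snps.tsv"),
        "phenotypes": os.path.join(out_dir, f"{prefix}.phenotypes.tsv"),
        "outcomes": os.path.join(out_dir, f"{prefix}.outcomes.tsv"),
        "manifest": os.path.join(out_dir, f"{prefix}.manifest.json"),
    }
    cohort.genotypes.rename_axis("subject_id").to_csv(paths["genotypes"], sep="\t")
    cohort.snps.rename_axis("snp_id").to_csv(paths["snps"], sep="\t")
    cohort.phenotypes.rename_axis("subject_id").to_csv(paths["phenotypes"], sep="\t")
    cohort.outcomes.rename_axis("subject_id").to_csv(paths["outcomes"], sep="\t")
    with open(paths["manifest"], "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, default=float)
    return paths


def write_summary_stats(associations: pd.DataFrame, path) -> None:
    """Write per-SNP associations to TSV in the canonical column order."""
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in associations.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns {missing!r}")
    associations.loc[:, SUMMARY_STAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV; checks snp_id uniqueness within trait."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"summary statistics missing columns {missing!r}")
    dup = df.duplicated(subset=["snp_id", "trait"])
    if dup.any():
        bad = df.loc[dup, "snp_id"].iloc[0]
        raise CohortParseError(f"duplicated snp_id {bad!r} within a trait")
    return df
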