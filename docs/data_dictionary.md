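# Data dictionary

All cohort tables are tab-delimited with a header row; missing values are
empty fields.  Subject identifiers must agree across the three tables.

## Genotypes (`*.genotypes.tsv` or VCF)

| column | meaning |
|---|---|
| `subject_id` | subject key (first column) |
| one column per SNP | effect-allele dosage in [0, 2]; imputed non-integers allowed |

VCF input (v4.x) is accepted instead: the `DS` FORMAT field is preferred,
`GT` is the fallback, ALT is the effect allele.

## SNP metadata (`*.snps.tsv`)

| column | unit / coding |
|---|---|
| `snp_id` | key, must match the dosage header |
| `effect_allele`, `other_allele` | allele whose count the dosage reports |
| `locus` | simulated cohorts only: LPA / LDL / NULL |
| `maf` | simulated cohorts only: generating minor-allele frequency |
| `true_effect` | simulated cohorts only: generating per-allele effect |

## Phenotypes (`*.phenotypes.tsv`)

| column | unit | notes |
|---|---|---|
| `subject_id` | — | key |
| `lpa_mass` | nmol/L | Lp(a) mass concentration; missing outside the 3.8–189 assay range |
| `apob_mass` | g/L | total apolipoprotein B |
| `total_c` | mmol/L | total cholesterol |
| `ldl_c` | mmol/L | LDL cholesterol |
| `hdl_c` | mmol/L | HDL cholesterol |
| `triglycerides` | mmol/L | |
| `age` | years | |
| `sex` | 0/1 | 1 = male |
| `bmi` | kg/m² | |
| `sbp` | mmHg | systolic blood pressure |
| `pc1` … `pc5` | unitless | genomic principal components |
| `on_lipid_lowering` | 0/1 | lipid-lowering therapy at baseline |

Derived on read (never stored): `remnant_c` = `total_c` − `ldl_c` −
`hdl_c` (mmol/L) and `apob_molar` = `apob_mass` × 1e9 / 550,000 (nmol/L).

## Outcomes (`*.outcomes.tsv`)

| column | unit | notes |
|---|---|---|
| `subject_id` | — | key |
| `prevalent_chd` | 0/1 | CHD at baseline |
| `incident_chd` | 0/1 | CHD during follow-up |
| `followup_years` | years | observed follow-up; 0 for prevalent cases |

## Summary statistics (`gwas_<trait>.tsv`)

One row per SNP × trait: `snp_id`, `effect_allele`, `other_allele`,
`eaf`, `beta` (trait units per effect allele; log OR per allele for
`chd`), `se`, `pvalue`, `n`, `trait`.

## Cluster files (`cluster_<name>.tsv`)

`snp_id`, `effect_allele` (apoB-raising), `other_allele`,
`apob_weight` (nmol/L apoB per raising allele, ≥ 0), `source_rule`.
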