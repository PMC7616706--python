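import numpy as np
import pandas as pd
import pytest

from particle_mr.io import Cohort
from particle_mr.simulate import SimulationConfig, simulate_cohort

PHENOTYPE_DEFAULTS = {
    "lpa_mass": 30.0,
    "apob_mass": 1.0,
    "total_c": 5.2,
    "ldl_c": 3.5,
    "hdl_c": 1.4,
    "triglycerides": 1.2,
    "age": 57.0,
    "sex": 0.0,
    "bmi": 27.0,
    "sbp": 138.0,
    "pc1": 0.0, "pc2": 0.0, "pc3": 0.0, "pc4": 0.0, "pc5": 0.0,
    "on_lipid_lowering": 0,
}


def make_tiny_cohort(dosages: dict, phenotypes: dict | None = None,
                     outcomes: dict | None = None,
                     effect_alleles: dict | None = None) -> Cohort:
    """Hand-built cohort for unit tests.

    ``dosages`` maps snp_id -> per-subject dosage list; phenotype columns
    not supplied are filled with constants, with ``total_c`` recomputed so
    the remnant identity holds when any lipid column is customised.
    """
    n = len(next(iter(dosages.values())))
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
    geno = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in dosages.items()},
                        index=idx)
    ph = {}
    for col, default in PHENOTYPE_DEFAULTS.items():
        val = (phenotypes or {}).get(col, default)
        ph[col] = np.broadcast_to(np.asarray(val, dtype=float), (n,)).copy()
    pheno = pd.DataFrame(ph, index=idx)
    oc = {
        "prevalent_chd": np.zeros(n, dtype=int),
        "incident_chd": np.zeros(n, dtype=int),
        "followup_years": np.full(n, 12.0),
    }
    for col, val in (outcomes or {}).items():
        oc[col] = np.broadcast_to(np.asarray(val), (n,)).copy()
    out = pd.DataFrame(oc, index=idx)
    ea = effect_alleles or {}
    snps = pd.DataFrame(
        {
            "effect_allele": [ea.get(s, ("A", "G"))[0] for s in geno.columns],
            "other_allele": [ea.get(s, ("A", "G"))[1] for s in geno.columns],
        },
        index=pd.Index(geno.columns, name="snp_id"),
    )
    return Cohort(geno, snps, pheno, out).validate()


@pytest.fixture(scope="session")
def small_cohort():
    """A 4000-subject simulated cohort shared across test modules."""
    cfg = SimulationConfig(n_subjects=4000, n_lpa_locus_snps=30, n_ldl_snps=20,
                           n_null_snps=20, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_associations(small_cohort):
    import warnings

    from particle_mr.gwas import associate

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assoc = {t: associate(small_cohort, t)
                 for t in ("lpa_mass", "apob_molar", "ldl_c", "remnant_c",
                           "triglycerides")}
        assoc["chd"] = associate(small_cohort, "chd", subject_filter="all")
    return assoc
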