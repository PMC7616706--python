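"""Polygenic scores, ventile stratification and hazard-ratio rescaling.

A cluster's polygenic score (PGS) for a subject is the weighted sum of
apoB-raising allele counts, each SNP weighted by its effect on molar apoB.
Ranking the cohort into ventiles (20 near-equal rank groups) of the score
and tabulating mean lipoprotein levels and incident CHD event rates gives a
model-light view of the dose-response; a Cox proportional-hazards fit on
the continuous score, rescaled through the least-squares slope of measured
apoB on the score, gives the hazard ratio per 50 nmol/L apoB.

The rescaling makes the result invariant to any rescaling of the weights:
multiplying the weights by c multiplies the log HR per score unit by 1/c
and the apoB slope by 1/c, leaving the HR per 50 nmol/L unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .clusters import SnpCluster
from .survival import CoxPHModel

DEFAULT_COX_COVARIATES = ("sex", "bmi", "age", "sbp")


class PgsError(RuntimeError):
    pass


@dataclass
class PgsResult:
    """Polygenic-score analysis output for one cluster."""

    cluster_name: str
    per_subject_score: pd.Series
    ventile_assignments: pd.Series
    ventile_summaries: pd.DataFrame
    apob_slope: float              # nmol/L of measured apoB per score unit
    log_hr_per_score_unit: float
    se_log_hr_per_score_unit: float
    scale_nmol: float = 50.0
    n_events: int = 0
    n_at_risk: int = 0
    cox_covariates: tuple = ()
    ties: str = "breslow"

    @property
    def log_hr_per_increment(self) -> float:
        return self.scale_nmol * self.log_hr_per_score_unit / self.apob_slope

    @property
    def hr_per_increment(self) -> float:
        return float(np.exp(self.log_hr_per_increment))

    @property
    def ci95_hr_per_increment(self) -> tuple:
        from scipy import stats

        z = stats.norm.ppf(0.975)
        factor = self.scale_nmol / self.apob_slope
        lo = (self.log_hr_per_score_unit - z * self.se_log_hr_per_score_unit) * factor
        hi = (self.log_hr_per_score_unit + z * self.se_log_hr_per_score_unit) * factor
        lo, hi = sorted((lo, hi))
        return (float(np.exp(lo)), float(np.exp(hi)))

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster_name,
            "apob_slope_nmol_per_score_unit": self.apob_slope,
            "log_hr_per_score_unit": self.log_hr_per_score_unit,
            "se_log_hr_per_score_unit": self.se_log_hr_per_score_unit,
            "scale_nmol": self.scale_nmol,
            "hr_per_increment": self.hr_per_increment,
            "ci95_hr_per_increment": list(self.ci95_hr_per_increment),
            "n_events": self.n_events,
            "n_at_risk": self.n_at_risk,
            "cox_covariates": list(self.cox_covariates),
            "ties": self.ties,
            "ventile_summaries": self.ventile_summaries.to_dict(orient="list"),
        }


class PolygenicScore(BaseEstimator, TransformerMixin):
    """Weighted apoB-raising allele count (sklearn transformer).

    ``fit`` aligns the cluster to a cohort's genotype coding (raising-allele
    dosage is the stored dosage, or ``2 - dosage`` where the cohort's effect
    allele is the cluster's other allele); ``transform`` returns one score
    per subject.
    """

    def __init__(self, cluster: SnpCluster):
        self.cluster = cluster

    def fit(self, cohort, y=None):
        missing = [s for s in self.cluster.snp_ids
                   if s not in cohort.genotypes.columns]
        if missing:
            raise PgsError(f"cluster SNP(s) absent from genotypes: {missing[:5]!r}")
        w = self.cluster.apob_weights
        if np.any(w < 0):
            raise PgsError("cluster weights must be apoB-raising (all >= 0)")
        flips, bad = [], []
        for s in self.cluster.snp_ids:
            ea_c = self.cluster.table.at[s, "effect_allele"]
            oa_c = self.cluster.table.at[s, "other_allele"]
            ea, oa = cohort.snps.at[s, "effect_allele"], cohort.snps.at[s, "other_allele"]
            if (ea, oa) == (ea_c, oa_c):
                flips.append(False)
            elif (ea, oa) == (oa_c, ea_c):
                flips.append(True)
            else:
                bad.append(s)
        if bad:
            raise PgsError(f"allele mismatch between cluster and cohort: {bad[:5]!r}")
        self.flip_ = np.asarray(flips)
        self.weights_ = w
        return self

    def transform(self, cohort) -> pd.Series:
        dos = cohort.dosage_matrix(self.cluster.snp_ids)
        dos = np.where(self.flip_, 2.0 - dos, dos)
        return pd.Series(dos @ self.weights_, index=cohort.genotypes.index,
                         name=f"pgs_{self.cluster.name}")


def compute_pgs(cohort, cluster: SnpCluster) -> pd.Series:
    """Per-subject PGS: sum of apoB weights times raising-allele dosages."""
    return PolygenicScore(cluster).fit(cohort).transform(cohort)


def ventile_table(scores: pd.Series, cohort, n_groups: int = 20) -> tuple:
    """Rank subjects into ventiles of the score and summarise each group.

    Groups have near-equal sizes (differing by at most one); ties are broken
    by stable subject order.  Returns ``(assignments, summaries)`` where
    ``assignments`` maps subject to ventile 1..n_groups and ``summaries``
    has per-ventile means of apoB (nmol/L), Lp(a) mass (nmol/L, in-range
    subjects), LDL-C (mmol/L) and the incident CHD event rate per
    person-year among subjects free of prevalent disease.
    """
    n = len(scores)
    if n < n_groups:
        raise PgsError(f"need at least {n_groups} subjects, got {n}")
    order = np.argsort(scores.to_numpy(), kind="mergesort")  # stable in ties
    assignment = np.empty(n, dtype=int)
    for v, chunk in enumerate(np.array_split(np.arange(n), n_groups), start=1):
        assignment[order[chunk]] = v
    assignments = pd.Series(assignment, index=scores.index, name="ventile")

    ph, oc = cohort.phenotypes, cohort.outcomes
    rows = []
    for v in range(1, n_groups + 1):
        m = assignment == v
        free = m & (oc["prevalent_chd"].to_numpy() == 0)
        person_years = float(oc["followup_years"].to_numpy()[free].sum())
        events = int(oc["incident_chd"].to_numpy()[free].sum())
        rows.append(
            {
                "ventile": v,
                "n": int(m.sum()),
                "mean_score": float(scores.to_numpy()[m].mean()),
                "mean_apob_molar": float(ph["apob_molar"].to_numpy()[m].mean()),
                "mean_lpa_mass": float(np.nanmean(ph["lpa_mass"].to_numpy()[m])),
                "mean_ldl_c": float(ph["ldl_c"].to_numpy()[m].mean()),
                "incident_events": events,
                "person_years": person_years,
                "event_rate_per_py": events / person_years if person_years > 0 else np.nan,
            }
        )
    return assignments, pd.DataFrame(rows)


def cox_hr_per_50(scores: pd.Series, cohort,
                  covariates=DEFAULT_COX_COVARIATES,
                  scale_nmol: float = 50.0, ties: str = "breslow",
                  untreated_slope_only: bool = False,
                  n_groups: int = 20) -> PgsResult:
    """Incident-CHD proportional-hazards analysis of a PGS, per 50 nmol/L apoB.

    Subjects with prevalent disease are excluded from the risk set.  The
    continuous-score Cox model (adjusting for ``covariates``) gives the log
    HR per score unit; the least-squares slope of measured molar apoB on the
    score (all scored subjects by default, untreated only on request)
    converts it to the ``scale_nmol`` apoB increment:
    ``hr = exp(scale * log_hr_per_score / apob_slope)``.
    """
    ph, oc = cohort.phenotypes, cohort.outcomes
    if float(np.var(scores.to_numpy())) == 0.0:
        raise PgsError("degenerate score (zero variance); apoB slope undefined")
    at_risk = (oc["prevalent_chd"].to_numpy() == 0) & \
              (oc["followup_years"].to_numpy() > 0)
    X = pd.DataFrame({"pgs": scores.to_numpy()[at_risk]})
    for c in covariates:
        X[c] = ph[c].to_numpy(dtype=float)[at_risk]
    model = CoxPHModel(ties=ties).fit(
        X, oc["followup_years"].to_numpy()[at_risk],
        oc["incident_chd"].to_numpy()[at_risk] == 1,
    )
    log_hr = float(model.coef_[0])
    se_log_hr = float(model.se_[0])

    slope_rows = np.ones(len(scores), dtype=bool)
    if untreated_slope_only:
        slope_rows &= ph["on_lipid_lowering"].to_numpy() == 0
    s = scores.to_numpy()[slope_rows]
    a = ph["apob_molar"].to_numpy(dtype=float)[slope_rows]
    sc = s - s.mean()
    denom = float(sc @ sc)
    if denom == 0.0:
        raise PgsError("degenerate score (zero variance); apoB slope undefined")
    apob_slope = float(sc @ (a - a.mean()) / denom)
    if apob_slope == 0.0:
        raise PgsError("zero apoB-on-score slope; per-increment scaling undefined")

    assignments, summaries = ventile_table(scores, cohort, n_groups=n_groups)
    return PgsResult(
        cluster_name=scores.name or "",
        per_subject_score=scores,
        ventile_assignments=assignments,
        ventile_summaries=summaries,
        apob_slope=apob_slope,
        log_hr_per_score_unit=log_hr,
        se_log_hr_per_score_unit=se_log_hr,
        scale_nmol=scale_nmol,
        n_events=model.n_events_,
        n_at_risk=model.n_subjects_,
        cox_covariates=tuple(covariates),
        ties=ties,
    )
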