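"""Summary-statistic Mendelian randomisation estimators.

Each estimator regresses per-SNP CHD log odds ratios on per-SNP apoB
effects (nmol/L per allele); the slope is the causal log OR per nmol/L of
apoB carried by the cluster's particle class, reported as an odds ratio per
a fixed apoB increment (default 50 nmol/L).

Estimators follow the scikit-learn protocol (``fit``, fitted attributes
with trailing underscores, ``get_params``/``set_params``) so they compose
with sklearn tooling; the module-level functions :func:`ivw`,
:func:`egger` and :func:`weighted_median` are thin wrappers returning a
frozen :class:`MrEstimate`.

* :class:`IvwEstimator` — inverse-variance-weighted estimator: exact
  zero-intercept weighted least squares with weights ``1/se_out**2``
  (fixed-effect SE; optional multiplicative random-effects inflation by
  ``sqrt(Q / (k - 1))`` when Cochran's Q exceeds its degrees of freedom).
* :class:`EggerEstimator` — weighted least squares with intercept after
  orienting all exposure betas non-negative; the intercept estimates
  directional pleiotropy and the SEs carry the usual multiplicative
  dispersion floored at 1.
* :class:`WeightedMedianEstimator` — weighted median of per-SNP ratio
  estimates with first-order (delta-method) inverse-variance weights and a
  parametric-bootstrap SE; consistent when at least half the weight comes
  from valid instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .clusters import SnpCluster, harmonise_to_cluster

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MrEstimate:
    """A Mendelian-randomisation result on the per-nmol/L apoB scale.

    ``theta`` is the log OR per nmol/L apoB; ``or_per_increment`` is
    ``exp(scale * theta)`` (default scale 50 nmol/L).
    """

    cluster_name: str
    method: str
    theta: float
    se_theta: float
    n_snps: int
    scale: float = 50.0
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    q_statistic: float | None = None
    inputs: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def or_per_increment(self) -> float:
        return float(np.exp(self.scale * self.theta))

    @property
    def ci95_theta(self) -> tuple:
        return (self.theta - Z95 * self.se_theta, self.theta + Z95 * self.se_theta)

    @property
    def ci95_or_per_increment(self) -> tuple:
        lo, hi = self.ci95_theta
        return (float(np.exp(self.scale * lo)), float(np.exp(self.scale * hi)))

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.theta) / self.se_theta))

    def to_dict(self) -> dict:
        d = {
            "cluster": self.cluster_name,
            "method": self.method,
            "theta_per_nmol": self.theta,
            "se_theta": self.se_theta,
            "scale_nmol": self.scale,
            "or_per_increment": self.or_per_increment,
            "ci95_or_per_increment": list(self.ci95_or_per_increment),
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
        }
        if self.egger_intercept is not None:
            d["egger_intercept"] = self.egger_intercept
            d["egger_intercept_se"] = self.egger_intercept_se
        if self.q_statistic is not None:
            d["q_statistic"] = self.q_statistic
        return d


def _validate(beta_exp, beta_out, se_out, min_snps: int):
    bx = np.asarray(beta_exp, dtype=float).ravel()
    by = np.asarray(beta_out, dtype=float).ravel()
    se = np.asarray(se_out, dtype=float).ravel()
    if not (bx.shape == by.shape == se.shape):
        raise ValueError("beta_exp, beta_out and se_out must be aligned")
    if bx.size < min_snps:
        raise ValueError(f"at least {min_snps} instruments required, got {bx.size}")
    if np.any(~np.isfinite(bx)) or np.any(~np.isfinite(by)) or np.any(~np.isfinite(se)):
        raise ValueError("non-finite inputs")
    if np.any(se <= 0):
        raise ValueError("se_out must be positive")
    return bx, by, se


class IvwEstimator(BaseEstimator):
    """Inverse-variance-weighted MR (zero-intercept WLS).

    Parameters
    ----------
    scale : float
        apoB increment (nmol/L) used for the reported odds ratio.
    random_effects : bool
        Multiply the fixed-effect SE by ``max(1, sqrt(Q / (k - 1)))``.
    """

    def __init__(self, scale: float = 50.0, random_effects: bool = False):
        self.scale = scale
        self.random_effects = random_effects

    def fit(self, beta_exp, beta_out, se_out):
        bx, by, se = _validate(beta_exp, beta_out, se_out, min_snps=1)
        w = 1.0 / se ** 2
        sxx = float(np.sum(w * bx * bx))
        if sxx == 0.0:
            raise ValueError("all exposure betas are zero; IVW estimate undefined")
        self.theta_ = float(np.sum(w * bx * by) / sxx)
        se_fixed = float(np.sqrt(1.0 / sxx))
        self.q_statistic_ = float(np.sum(w * (by - self.theta_ * bx) ** 2))
        self.n_snps_ = int(bx.size)
        if self.random_effects and self.n_snps_ > 1:
            infl = max(1.0, np.sqrt(self.q_statistic_ / (self.n_snps_ - 1)))
        else:
            infl = 1.0
        self.se_theta_ = se_fixed * infl
        return self

    def to_estimate(self, cluster_name: str = "", inputs=None) -> MrEstimate:
        method = "ivw_re" if self.random_effects else "ivw"
        return MrEstimate(cluster_name, method, self.theta_, self.se_theta_,
                          self.n_snps_, self.scale, q_statistic=self.q_statistic_,
                          inputs=inputs)


class EggerEstimator(BaseEstimator):
    """MR-Egger: intercept-including WLS, tolerant of directional pleiotropy."""

    def __init__(self, scale: float = 50.0):
        self.scale = scale

    def fit(self, beta_exp, beta_out, se_out):
        bx, by, se = _validate(beta_exp, beta_out, se_out, min_snps=3)
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip  # orient exposure effects non-negative
        w = 1.0 / se ** 2
        X = np.column_stack([np.ones_like(bx), bx])
        XtWX = X.T @ (w[:, None] * X)
        XtWy = X.T @ (w * by)
        coef = np.linalg.solve(XtWX, XtWy)
        resid = by - X @ coef
        dof = bx.size - 2
        dispersion = max(1.0, float((w * resid ** 2).sum() / dof)) if dof > 0 else 1.0
        cov = np.linalg.inv(XtWX) * dispersion
        self.intercept_, self.theta_ = float(coef[0]), float(coef[1])
        self.intercept_se_ = float(np.sqrt(cov[0, 0]))
        self.se_theta_ = float(np.sqrt(cov[1, 1]))
        self.n_snps_ = int(bx.size)
        return self

    def to_estimate(self, cluster_name: str = "", inputs=None) -> MrEstimate:
        return MrEstimate(cluster_name, "egger", self.theta_, self.se_theta_,
                          self.n_snps_, self.scale,
                          egger_intercept=self.intercept_,
                          egger_intercept_se=self.intercept_se_, inputs=inputs)


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of per-SNP ratio estimates.

    Weights are proportional to the inverse first-order variance of each
    ratio, ``beta_exp**2 / se_out**2``; instruments with a zero exposure
    beta are dropped with a warning.  The SE comes from a parametric
    bootstrap of the outcome betas.
    """

    def __init__(self, scale: float = 50.0, n_boot: int = 1000, seed: int = 0):
        self.scale = scale
        self.n_boot = n_boot
        self.seed = seed

    @staticmethod
    def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order]
        w = w / w.sum()
        cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
        if cum[0] >= 0.5:
            return float(r[0])
        if cum[-1] <= 0.5:
            return float(r[-1])
        return float(np.interp(0.5, cum, r))

    def fit(self, beta_exp, beta_out, se_out):
        bx, by, se = _validate(beta_exp, beta_out, se_out, min_snps=3)
        nz = bx != 0.0
        if not nz.all():
            warnings.warn(f"dropping {int((~nz).sum())} instrument(s) with zero "
                          "exposure beta from the weighted median")
        bx, by, se = bx[nz], by[nz], se[nz]
        if bx.size < 3:
            raise ValueError("fewer than 3 usable instruments for the weighted median")
        ratios = by / bx
        weights = bx ** 2 / se ** 2
        self.theta_ = self._weighted_median(ratios, weights)
        rng = np.random.default_rng(self.seed)
        draws = np.empty(self.n_boot)
        for b in range(self.n_boot):
            by_b = by + se * rng.standard_normal(bx.size)
            draws[b] = self._weighted_median(by_b / bx, weights)
        self.se_theta_ = float(draws.std(ddof=1))
        self.n_snps_ = int(bx.size)
        return self

    def to_estimate(self, cluster_name: str = "", inputs=None) -> MrEstimate:
        return MrEstimate(cluster_name, "weighted_median", self.theta_,
                          self.se_theta_, self.n_snps_, self.scale, inputs=inputs)


def ivw(beta_exp, beta_out, se_out, scale: float = 50.0,
        random_effects: bool = False, cluster_name: str = "") -> MrEstimate:
    """Inverse-variance-weighted MR estimate (see :class:`IvwEstimator`)."""
    return IvwEstimator(scale, random_effects).fit(beta_exp, beta_out, se_out) \
        .to_estimate(cluster_name)


def egger(beta_exp, beta_out, se_out, scale: float = 50.0,
          cluster_name: str = "") -> MrEstimate:
    """MR-Egger estimate (see :class:`EggerEstimator`)."""
    return EggerEstimator(scale).fit(beta_exp, beta_out, se_out).to_estimate(cluster_name)


def weighted_median(beta_exp, beta_out, se_out, scale: float = 50.0,
                    n_boot: int = 1000, seed: int = 0,
                    cluster_name: str = "") -> MrEstimate:
    """Weighted-median MR estimate (see :class:`WeightedMedianEstimator`)."""
    return WeightedMedianEstimator(scale, n_boot, seed).fit(beta_exp, beta_out, se_out) \
        .to_estimate(cluster_name)


def run_mr_for_cluster(cluster: SnpCluster, assoc_apob: pd.DataFrame,
                       assoc_chd: pd.DataFrame, scale_nmol: float = 50.0,
                       seed: int = 0) -> dict:
    """All three MR methods for one cluster; IVW is the primary result.

    ``assoc_chd`` may come from the same cohort (one-sample design) or from
    an external summary-statistics file (two-sample replication); when the
    outcome set covers only part of the cluster the analysis runs on the
    intersection and the missing SNPs are logged.  Alleles are harmonised to
    the cluster's apoB-raising orientation; irreconcilable allele pairs are
    a hard error.
    """
    exp = harmonise_to_cluster(cluster, assoc_apob, require_all=True)
    out = harmonise_to_cluster(cluster, assoc_chd, require_all=False)
    common = [s for s in cluster.snp_ids if s in out.index]
    missing = sorted(set(cluster.snp_ids) - set(common))
    if missing:
        warnings.warn(
            f"{len(missing)} cluster SNP(s) absent from the outcome statistics; "
            f"running on the {len(common)}-SNP intersection: missing {missing[:5]!r}"
        )
    bx = exp.loc[common, "beta"].to_numpy(dtype=float)
    by = out.loc[common, "beta"].to_numpy(dtype=float)
    se = out.loc[common, "se"].to_numpy(dtype=float)
    inputs = pd.DataFrame(
        {"snp_id": common, "beta_apob": bx, "beta_chd": by, "se_chd": se}
    )
    results = {
        "ivw": IvwEstimator(scale_nmol).fit(bx, by, se)
        .to_estimate(cluster.name, inputs),
        "ivw_re": IvwEstimator(scale_nmol, random_effects=True).fit(bx, by, se)
        .to_estimate(cluster.name, inputs),
    }
    if len(common) >= 3:
        results["egger"] = EggerEstimator(scale_nmol).fit(bx, by, se) \
            .to_estimate(cluster.name, inputs)
        results["weighted_median"] = WeightedMedianEstimator(scale_nmol, seed=seed) \
            .fit(bx, by, se).to_estimate(cluster.name, inputs)
    return results
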