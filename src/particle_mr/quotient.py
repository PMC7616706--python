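"""The CHD risk quotient: relative per-particle atherogenicity.

The quotient divides the CHD log odds ratio per unit of genetically
predicted Lp(a)-apoB by the log odds ratio per the same unit of LDL-apoB.
Because both numerator and denominator are per the *same* apoB increment,
the increment cancels and the quotient is a dimensionless per-particle
risk ratio (log-OR scale).

Confidence intervals come from a bootstrap: the parametric mode draws the
two log ORs independently from normal distributions with their estimated
SEs (the two clusters are disjoint SNP sets) and takes empirical
percentiles of the ratio; the nonparametric mode resamples SNPs within
each cluster and recomputes the inverse-variance-weighted estimate per
replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mr import IvwEstimator, MrEstimate


@dataclass
class RiskQuotient:
    """Ratio of two log odds ratios with a bootstrap confidence interval."""

    q: float
    ci95: tuple
    n_boot: int
    method: str               # "parametric" | "nonparametric"
    seed: int
    unstable_fraction: float  # bootstrap replicates whose denominator crossed 0
    flagged: bool             # True when >1% of replicates were unstable
    est_lpa: MrEstimate | None = None
    est_ldl: MrEstimate | None = None

    def to_dict(self) -> dict:
        d = {
            "quotient": self.q,
            "ci95": list(self.ci95),
            "n_boot": self.n_boot,
            "method": self.method,
            "seed": self.seed,
            "unstable_fraction": self.unstable_fraction,
            "flagged": self.flagged,
        }
        if self.est_lpa is not None:
            d["numerator"] = self.est_lpa.to_dict()
        if self.est_ldl is not None:
            d["denominator"] = self.est_ldl.to_dict()
        return d


def quotient(est_lpa: MrEstimate, est_ldl: MrEstimate) -> float:
    """Point estimate: numerator log OR divided by denominator log OR.

    Both estimates must be on the same per-nmol/L (equivalently, the same
    per-increment) scale; the increment cancels in the ratio.  A weak
    denominator (|theta| < 3 SE) triggers an instability warning; a zero
    denominator is an error.
    """
    if est_lpa.scale != est_ldl.scale:
        raise ValueError(
            f"estimates use different apoB increments ({est_lpa.scale} vs {est_ldl.scale})"
        )
    if est_ldl.theta == 0.0:
        raise ZeroDivisionError("denominator log OR is zero; quotient undefined")
    if abs(est_ldl.theta) < 3.0 * est_ldl.se_theta:
        warnings.warn(
            "denominator log OR is within 3 SE of zero; the quotient is unstable"
        )
    return float(est_lpa.theta / est_ldl.theta)


def bootstrap_ci(est_lpa: MrEstimate, est_ldl: MrEstimate,
                 n_boot: int = 100_000, seed: int = 1,
                 method: str = "parametric") -> RiskQuotient:
    """Bootstrap 95% CI for the risk quotient.

    Parametric mode (default): draw ``theta_lpa* ~ N(theta_lpa, se^2)`` and
    ``theta_ldl* ~ N(theta_ldl, se^2)`` independently and take the 2.5th and
    97.5th percentiles of the ratio.  Nonparametric mode: resample SNPs with
    replacement within each cluster (requires per-SNP inputs on the
    estimates) and recompute the IVW estimate per replicate.

    Replicates whose denominator changes sign relative to the point estimate
    are recorded as unstable; if more than 1% are unstable the interval is
    flagged.  With both SEs zero the interval degenerates to the point
    estimate.
    """
    q = quotient(est_lpa, est_ldl)
    rng = np.random.default_rng(seed)
    if method == "parametric":
        if est_lpa.se_theta == 0.0 and est_ldl.se_theta == 0.0:
            return RiskQuotient(q, (q, q), n_boot, method, seed, 0.0, False,
                                est_lpa, est_ldl)
        num = rng.normal(est_lpa.theta, est_lpa.se_theta, n_boot)
        den = rng.normal(est_ldl.theta, est_ldl.se_theta, n_boot)
    elif method == "nonparametric":
        if est_lpa.inputs is None or est_ldl.inputs is None:
            raise ValueError(
                "nonparametric bootstrap needs per-SNP inputs on both estimates"
            )
        num = np.empty(n_boot)
        den = np.empty(n_boot)
        for side, est, out in ((0, est_lpa, num), (1, est_ldl, den)):
            bx = est.inputs["beta_apob"].to_numpy(dtype=float)
            by = est.inputs["beta_chd"].to_numpy(dtype=float)
            se = est.inputs["se_chd"].to_numpy(dtype=float)
            k = bx.size
            est_ivw = IvwEstimator(scale=est.scale)
            for b in range(n_boot):
                idx = rng.integers(0, k, k)
                out[b] = est_ivw.fit(bx[idx], by[idx], se[idx]).theta_
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")

    sign = np.sign(est_ldl.theta)
    unstable = np.sign(den) != sign
    frac_unstable = float(unstable.mean())
    ratios = num / den
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    flagged = frac_unstable > 0.01
    if flagged:
        warnings.warn(
            f"{100 * frac_unstable:.1f}% of bootstrap replicates had a "
            "denominator crossing zero; the interval may be unreliable"
        )
    return RiskQuotient(q, (float(lo), float(hi)), n_boot, method, seed,
                        frac_unstable, flagged, est_lpa, est_ldl)
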