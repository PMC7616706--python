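"""Cox proportional-hazards regression by Newton-Raphson.

Partial-likelihood fit with Breslow tie handling by default (Efron
available), Newton iterations to a relative log-likelihood tolerance of
1e-9 with step-halving, and SEs from the inverse observed information.
Written against the standard counting-process formulation: the risk set at
an event time is everyone still under follow-up at that time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge; carries the iteration trace."""


class CoxPHModel:
    """Proportional-hazards model for right-censored data.

    Parameters
    ----------
    ties : {"breslow", "efron"}
    tol : float
        Relative log-partial-likelihood convergence tolerance.
    max_iter : int

    Attributes (after fit)
    ----------------------
    coef_ : ndarray, log hazard ratios per covariate unit
    se_ : ndarray
    loglik_ : float
    n_iter_ : int
    feature_names_ : list of str
    """

    def __init__(self, ties: str = "breslow", tol: float = 1e-9, max_iter: int = 60):
        if ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    # -- partial likelihood, gradient, information -----------------------
    def _loglik_parts(self, beta, X, order, first, counts, tied_slices):
        n, p = X.shape
        eta = X @ beta
        r = np.exp(eta - eta.max())  # stabilised; constants cancel in ratios
        log_shift = eta.max()
        rX = r[:, None] * X
        rXX = np.einsum("n,ni,nj->nij", r, X, X)
        # reverse cumulative sums over subjects ordered by ascending time
        R0 = np.cumsum(r[order][::-1])[::-1]
        R1 = np.cumsum(rX[order][::-1], axis=0)[::-1]
        R2 = np.cumsum(rXX[order][::-1], axis=0)[::-1]

        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for k, i0 in enumerate(first):
            rows = tied_slices[k]          # indices (original) of tied events
            d = counts[k]
            sum_eta = float(eta[rows].sum())
            if self.ties == "breslow":
                S0, S1, S2 = R0[i0], R1[i0], R2[i0]
                ll += sum_eta - d * (np.log(S0) + log_shift)
                mean1 = S1 / S0
                grad += X[rows].sum(axis=0) - d * mean1
                info += d * (S2 / S0 - np.outer(mean1, mean1))
            else:  # efron
                s0t = float(r[rows].sum())
                s1t = rX[rows].sum(axis=0)
                s2t = rXX[rows].sum(axis=0)
                ll += sum_eta
                grad += X[rows].sum(axis=0)
                for l in range(d):
                    f = l / d
                    S0 = R0[i0] - f * s0t
                    S1 = R1[i0] - f * s1t
                    S2 = R2[i0] - f * s2t
                    ll -= np.log(S0) + log_shift
                    mean1 = S1 / S0
                    grad -= mean1
                    info += S2 / S0 - np.outer(mean1, mean1)
        return ll, grad, info

    def fit(self, X, duration, event):
        Xdf = pd.DataFrame(X)
        self.feature_names_ = [str(c) for c in Xdf.columns]
        X = Xdf.to_numpy(dtype=float)
        t = np.asarray(duration, dtype=float)
        e = np.asarray(event).astype(bool)
        if X.ndim != 2 or X.shape[0] != t.size or t.size != e.size:
            raise ValueError("X, duration and event must be aligned")
        if np.any(t < 0) or np.any(~np.isfinite(t)):
            raise ValueError("durations must be finite and non-negative")
        if not e.any():
            raise ValueError("no events in the risk set")
        self._center_ = X.mean(axis=0)
        Xc = X - self._center_  # centring leaves the partial likelihood invariant

        order = np.argsort(t, kind="mergesort")
        t_sorted = t[order]
        # distinct event times -> position of their risk set in the sorted array
        ev_times = np.unique(t[e])
        first = np.searchsorted(t_sorted, ev_times, side="left")
        tied_slices, counts = [], []
        for tt in ev_times:
            rows = np.flatnonzero(e & (t == tt))
            tied_slices.append(rows)
            counts.append(len(rows))
        counts = np.asarray(counts)

        beta = np.zeros(Xc.shape[1])
        ll, grad, info = self._loglik_parts(beta, Xc, order, first, counts, tied_slices)
        trace = [ll]
        converged = False
        for it in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix at iter {it}; "
                                       f"trace={trace}") from exc
            # step-halving keeps the likelihood non-decreasing
            for _ in range(30):
                ll_new, grad_new, info_new = self._loglik_parts(
                    beta + step, Xc, order, first, counts, tied_slices
                )
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            beta = beta + step
            trace.append(ll_new)
            if abs(ll_new - ll) < self.tol * (abs(ll) + 1.0):
                ll, grad, info = ll_new, grad_new, info_new
                converged = True
                break
            ll, grad, info = ll_new, grad_new, info_new
        if not converged:
            raise ConvergenceError(
                f"Cox fit did not converge in {self.max_iter} iterations; trace={trace}"
            )
        self.coef_ = beta
        self.information_ = info
        self.cov_ = np.linalg.inv(info)
        self.se_ = np.sqrt(np.diag(self.cov_))
        self.loglik_ = float(ll)
        self.n_iter_ = it
        self.n_events_ = int(e.sum())
        self.n_subjects_ = int(t.size)
        return self

    def summary(self) -> pd.DataFrame:
        from scipy import stats

        z = self.coef_ / self.se_
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_,
                "hr": np.exp(self.coef_),
                "z": z,
                "pvalue": 2.0 * stats.norm.sf(np.abs(z)),
            },
            index=self.feature_names_,
        )
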