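"""Fine-Gray subdistribution-hazard regression with competing death.

Treatment failure (event 1) competes with death from other causes
(event 2); censoring is event 0.  The Fine-Gray model regresses the
subdistribution hazard of failure: subjects with a competing event remain
in later risk sets with inverse-probability-of-censoring weights
w_i(t) = G(t-)/G(T_i-) from the Kaplan-Meier estimator G of the censoring
distribution (Geskus weighting).  Estimation maximizes the weighted Cox
partial likelihood (Breslow ties) by Newton iterations; the baseline
subdistribution cumulative hazard uses the weighted Breslow estimator, and

    CIF(t | x) = 1 - exp(-Lambda0(t) * exp(x' beta)).

Prediction accuracy is summarized by a competing-risk-adapted concordance
index and the IPCW Brier score / integrated Brier score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "FineGrayFitter",
    "fit_fine_gray",
    "cumulative_incidence",
    "concordance_index",
    "brier_curve",
    "integrated_brier",
    "export_competing_risk_frame",
]


def _km_censoring(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimator of the censoring survival G.

    Returns a step-function evaluator ``G(t, before=False)``; ``before=True``
    gives the left limit G(t-).
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    cens = (event[order] == 0).astype(float)
    uniq = np.unique(t)
    n = len(t)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    d_cens = np.array([cens[t == u].sum() for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(at_risk > 0, 1.0 - d_cens / at_risk, 1.0)
    surv = np.cumprod(factors)

    def G(tt, before=False):
        tt = np.asarray(tt, dtype=float)
        side = "left" if before else "right"
        idx = np.searchsorted(uniq, tt, side=side) - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
        return out if out.ndim else float(out)

    return G


@dataclass
class _FGData:
    X: np.ndarray
    time: np.ndarray
    event: np.ndarray


class FineGrayFitter(BaseEstimator):
    """Fine-Gray subdistribution-hazard model.

    Parameters
    ----------
    standardize : bool
        Center/scale covariates on the training data (mean 0, sd 1); the
        stored mean/scale are re-applied at prediction time.
    max_iter, tol : Newton iteration controls (gradient max-norm).
    """

    def __init__(self, standardize: bool = True, max_iter: int = 100,
                 tol: float = 1e-8):
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -----------------------------------------------------------
    def fit(self, X, time, event):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(np.asarray(time)) != 1:
            X = X.T
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if np.any(time < 0):
            raise ValueError("times must be non-negative")
        if not np.all(np.isin(event, (0, 1, 2))):
            raise ValueError("event codes must be 0 (censor), 1 (failure), 2 (death)")
        if (event == 1).sum() < 1:
            raise ValueError("need at least one failure event")

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_

        G = _km_censoring(time, event)
        fail_times = np.unique(time[event == 1])
        # weight matrix: rows = failure times, cols = subjects
        n = len(time)
        W = np.zeros((len(fail_times), n))
        for r, t in enumerate(fail_times):
            at_risk = time >= t
            W[r, at_risk] = 1.0
            comp = (event == 2) & (time < t)
            if comp.any():
                gt = G(t, before=True)
                gi = G(time[comp], before=True)
                with np.errstate(divide="ignore", invalid="ignore"):
                    W[r, comp] = np.where(gi > 0, gt / gi, 0.0)
        d_counts = np.array([(time == t) & (event == 1) for t in fail_times]).sum(axis=1)
        x_events = np.array(
            [Z[(time == t) & (event == 1)].sum(axis=0) for t in fail_times]
        )

        beta = np.zeros(Z.shape[1])
        prev_ll = -np.inf
        for it in range(self.max_iter):
            ll, grad, hess = self._ll_grad_hess(beta, Z, W, d_counts, x_events)
            gnorm = np.max(np.abs(grad))
            if gnorm < self.tol:
                break
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                raise RuntimeError(
                    "Fine-Gray Hessian is singular (possible complete separation)"
                )
            # step-halving safeguard
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, _, _ = self._ll_grad_hess(
                    cand, Z, W, d_counts, x_events, derivatives=False
                )
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            if np.max(np.abs(beta)) > 50:
                raise RuntimeError(
                    "Fine-Gray coefficients diverging (complete separation?)"
                )
            prev_ll = ll
        else:
            raise RuntimeError(
                f"Fine-Gray Newton did not converge in {self.max_iter} iterations "
                f"(|grad| = {gnorm:.3g})"
            )
        self.n_iter_ = it + 1
        self.converged_ = True
        self.coef_ = beta
        _, _, hess = self._ll_grad_hess(beta, Z, W, d_counts, x_events)
        try:
            cov = np.linalg.inv(hess)
            self.se_ = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            self.se_ = np.full(len(beta), np.nan)

        # weighted Breslow baseline subdistribution cumulative hazard
        eta = Z @ beta
        rexp = np.exp(eta)
        s0 = (W * rexp[None, :]).sum(axis=1)
        increments = d_counts / s0
        self.baseline_times_ = fail_times
        self.baseline_cumhaz_ = np.cumsum(increments)
        self._train = _FGData(Z, time, event)
        return self

    @staticmethod
    def _ll_grad_hess(beta, Z, W, d_counts, x_events, derivatives=True):
        eta = Z @ beta
        rexp = np.exp(np.clip(eta, -500, 500))
        R = W * rexp[None, :]  # (T, n)
        s0 = R.sum(axis=1)
        ll = float((x_events @ beta).sum() - (d_counts * np.log(s0)).sum())
        if not derivatives:
            return ll, None, None
        s1 = R @ Z  # (T, p)
        xbar = s1 / s0[:, None]
        grad = x_events.sum(axis=0) - (d_counts[:, None] * xbar).sum(axis=0)
        p = Z.shape[1]
        hess = np.zeros((p, p))
        # sum_t d_t * (S2/S0 - xbar xbar')
        for r in range(len(s0)):
            s2 = (R[r][:, None] * Z).T @ Z
            hess += d_counts[r] * (s2 / s0[r] - np.outer(xbar[r], xbar[r]))
        return ll, grad, hess

    # -- prediction --------------------------------------------------------
    def _linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.mean_) / self.scale_) @ self.coef_

    def predict_risk_score(self, X) -> np.ndarray:
        """x' beta on the standardized scale: higher = earlier failure."""
        return self._linear_predictor(X)

    def predict_cumulative_incidence(self, X, times) -> np.ndarray:
        """CIF(t | x) on a grid; shape (n_cases, n_times).

        Beyond the last observed failure time the CIF is held constant.
        """
        times = np.asarray(times, dtype=float)
        eta = self._linear_predictor(X)
        idx = np.searchsorted(self.baseline_times_, times, side="right") - 1
        lam = np.where(idx >= 0, self.baseline_cumhaz_[np.clip(idx, 0, None)], 0.0)
        cif = 1.0 - np.exp(-np.outer(np.exp(eta), lam))
        return np.clip(cif, 0.0, 1.0)


def fit_fine_gray(X, time, event, **kwargs) -> FineGrayFitter:
    """Convenience wrapper: fit a :class:`FineGrayFitter`."""
    return FineGrayFitter(**kwargs).fit(X, time, event)


def cumulative_incidence(fit: FineGrayFitter, X, times) -> np.ndarray:
    return fit.predict_cumulative_incidence(X, times)


def concordance_index(risk_scores, time, event) -> float:
    """Competing-risk-adapted concordance for failure (event 1).

    A pair (i, j) with i failing at T_i is usable when j is still
    event-free beyond T_i, or j had the competing event (so j is known
    never to fail).  Concordant when the failing case has the higher
    predicted risk; ties in risk count 1/2.
    """
    risk = np.asarray(risk_scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    usable = 0
    conc = 0.0
    for i in np.flatnonzero(event == 1):
        cmp_later = (time > time[i]) | ((event == 2) & (time <= time[i]))
        cmp_later[i] = False
        for j in np.flatnonzero(cmp_later):
            usable += 1
            if risk[i] > risk[j]:
                conc += 1.0
            elif risk[i] == risk[j]:
                conc += 0.5
    if usable == 0:
        raise ValueError("no usable pairs for concordance")
    return conc / usable


def brier_curve(
    fit: FineGrayFitter, X, time, event, times
) -> Tuple[np.ndarray, np.ndarray]:
    """IPCW Brier score of the predicted failure CIF at each evaluation time.

    Weights: 1/G(T_i-) for subjects with any event by t, 1/G(t) for
    subjects still at risk, 0 for subjects censored by t.  Times where the
    censoring survival hits zero are excluded.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    times = np.asarray(times, dtype=float)
    G = _km_censoring(time, event)
    cif = fit.predict_cumulative_incidence(X, times)
    out_t, out_b = [], []
    n = len(time)
    for k, t in enumerate(times):
        g_t = G(t)
        happened = (time <= t) & (event != 0)
        at_risk = time > t
        w = np.zeros(n)
        gi = G(time[happened], before=True)
        ok_h = gi > 0
        w[np.flatnonzero(happened)[ok_h]] = 1.0 / gi[ok_h]
        if at_risk.any():
            if g_t <= 0:
                continue
            w[at_risk] = 1.0 / g_t
        y = ((time <= t) & (event == 1)).astype(float)
        out_t.append(t)
        out_b.append(float(np.mean(w * (y - cif[:, k]) ** 2)))
    return np.asarray(out_t), np.asarray(out_b)


def integrated_brier(times: np.ndarray, briers: np.ndarray) -> float:
    """Time-averaged Brier score by trapezoidal integration."""
    times = np.asarray(times, dtype=float)
    briers = np.asarray(briers, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two time points to integrate")
    return float(np.trapezoid(briers, times) / (times[-1] - times[0]))


def export_competing_risk_frame(X, time, event, feature_names=None):
    """Long-format frame (time, event, covariates) directly consumable by
    external survival packages for cross-checking."""
    import pandas as pd

    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = feature_names or [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "event", np.asarray(event, dtype=int))
    df.insert(0, "time", np.asarray(time, dtype=float))
    return df
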