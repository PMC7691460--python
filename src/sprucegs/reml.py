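"""Average-information REML for variance-component models.

Fits y = X beta + sum_k Z_k u_k + e with u_k ~ N(0, theta_k K_k) and a
block-diagonal residual with one variance per site, by maximizing the
restricted log-likelihood. Updates are average-information (AI) steps with
step-halving and an EM fallback whenever an AI candidate leaves the
parameter space or decreases the likelihood; negative variances are
projected to a small floor. The trait is standardized internally so floors
and tolerances are scale-free; all reported quantities are returned on the
original scale.

This is deliberately a dense-matrix implementation: breeding-trial data
sets (a few thousand trees) fit comfortably, and dense V^-1 gives the exact
trace terms the AI/EM updates need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RandomTerm", "RemlResult", "RemlError", "ai_reml"]

_LOG2PI = np.log(2.0 * np.pi)


class RemlError(RuntimeError):
    """REML failure; carries the iteration trace for diagnosis."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class RandomTerm:
    """One random effect: covariance among observations plus a predictor.

    ``V`` is the n x n covariance structure among the observations
    (Z K Z' — for a selection/incidence Z this is K indexed by the observed
    levels, repeats included). ``C_pred`` is the cross-covariance structure
    between every prediction target and the observations (K[targets, obs]),
    so the BLUP of all targets is ``theta * C_pred @ P y``.
    """

    name: str
    V: np.ndarray
    C_pred: np.ndarray
    pred_ids: np.ndarray
    q: int  # number of distinct levels (EM denominator)


@dataclass
class RemlResult:
    theta: np.ndarray
    param_names: list
    loglik: float
    beta: np.ndarray
    blups: dict
    ai_cov: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    rank_X: int
    trace: list = field(default_factory=list)


def _loglik_only(y, X, terms, site_masks, theta, n_terms):
    """Restricted log-likelihood at theta (standardized scale)."""
    n, p = X.shape
    V = np.zeros((n, n))
    for k, t in enumerate(terms):
        V += theta[k] * t.V
    d = np.zeros(n)
    for s, mask in enumerate(site_masks):
        d[mask] = theta[n_terms + s]
    V[np.diag_indices(n)] += d
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    try:
        cfx = cho_factor(XtViX, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None
    logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    beta = cho_solve(cfx, X.T @ Viy)
    Py = Viy - ViX @ beta
    ll = -0.5 * (logdetV + logdetX + float(y @ Py) + (n - p) * _LOG2PI)
    return ll, (cf, cfx, ViX, beta, Py)


def ai_reml(
    y,
    X,
    terms: list,
    site_codes,
    start=None,
    max_iter: int = 200,
    ll_tol: float = 1e-6,
    par_tol: float = 1e-8,
    floor: float = 1e-8,
) -> RemlResult:
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    site_codes = np.asarray(site_codes)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X disagree on n")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")

    sd = float(np.std(y))
    if sd <= 0:
        raise RemlError("trait has zero variance")
    ys = y / sd

    sites = pd.unique(site_codes)
    site_masks = [site_codes == s for s in sites]
    n_terms = len(terms)
    n_par = n_terms + len(sites)
    names = [t.name for t in terms] + [f"residual[{s}]" for s in sites]

    if start is None:
        beta0, *_ = np.linalg.lstsq(X, ys, rcond=None)
        v0 = float(np.var(ys - X @ beta0))
        theta = np.empty(n_par)
        theta[:n_terms] = 0.5 * v0 / max(n_terms, 1)
        theta[n_terms:] = 0.5 * v0 if n_terms else v0
    else:
        theta = np.asarray(start, dtype=float) / sd**2
    theta = np.maximum(theta, floor)

    q_res = [int(m.sum()) for m in site_masks]
    trace = []
    ll_prev = -np.inf
    converged = False
    AI = np.eye(n_par)
    ll, aux = _loglik_only(ys, X, terms, site_masks, theta, n_terms)
    if not np.isfinite(ll):
        raise RemlError("initial likelihood is not finite", trace)

    for it in range(1, max_iter + 1):
        cf, cfx, ViX, beta, Py = aux
        Vi = cho_solve(cf, np.eye(n))
        P = Vi - ViX @ cho_solve(cfx, ViX.T)

        # score and AI working vectors
        tvecs = np.empty((n_par, n))
        trPV = np.empty(n_par)
        for k, t in enumerate(terms):
            tvecs[k] = t.V @ Py
            trPV[k] = float(np.sum(P * t.V))
        diagP = np.diag(P)
        for s, mask in enumerate(site_masks):
            v = np.zeros(n)
            v[mask] = Py[mask]
            tvecs[n_terms + s] = v
            trPV[n_terms + s] = float(diagP[mask].sum())
        yPVPy = tvecs @ Py
        score = -0.5 * (trPV - yPVPy)
        PT = P @ tvecs.T
        AI = 0.5 * (tvecs @ PT)

        trace.append((it, ll * 1.0, (theta * sd**2).copy()))

        # --- propose an update ------------------------------------------
        def em_step(th):
            qs = np.array([t.q for t in terms] + q_res, dtype=float)
            return np.maximum(th + th**2 * (yPVPy - trPV) / qs, floor)

        def ai_delta():
            """AI step; components pushed below zero are pinned to the floor
            and the system re-solved in the remaining subspace."""
            free = np.ones(n_par, dtype=bool)
            for _ in range(n_par):
                idx = np.where(free)[0]
                if len(idx) == 0:
                    return None
                try:
                    d_free = np.linalg.solve(AI[np.ix_(idx, idx)], score[idx])
                except np.linalg.LinAlgError:
                    return None
                cand = np.full(n_par, floor)
                cand[idx] = theta[idx] + d_free
                bad = idx[cand[idx] <= 0]
                if len(bad) == 0:
                    return cand
                free[bad] = False
            return None

        candidate = None
        cand0 = ai_delta()
        if cand0 is not None:
            step = 1.0
            for _ in range(4):
                cand = theta + step * (cand0 - theta)
                if np.all(cand > 0):
                    ll_c, aux_c = _loglik_only(ys, X, terms, site_masks, cand, n_terms)
                    if ll_c >= ll - 1e-10:
                        candidate = (cand, ll_c, aux_c)
                        break
                step *= 0.5
        if candidate is None:
            cand = em_step(theta)
            ll_c, aux_c = _loglik_only(ys, X, terms, site_masks, cand, n_terms)
            if not np.isfinite(ll_c):
                raise RemlError("likelihood became non-finite during EM", trace)
            candidate = (cand, ll_c, aux_c)

        new_theta, new_ll, new_aux = candidate
        new_theta = np.maximum(new_theta, floor)
        # components at the boundary are excluded from the parameter test
        interior = new_theta > 100 * floor
        if interior.any():
            rel = np.max(
                np.abs(new_theta[interior] - theta[interior])
                / np.maximum(np.abs(theta[interior]), 1e-12)
            )
        else:
            rel = 0.0
        d_ll = new_ll - ll
        theta, ll, aux = new_theta, new_ll, new_aux

        if (abs(d_ll) < ll_tol and rel < par_tol) or abs(d_ll) < 1e-12:
            converged = True
            break

    if not converged and abs(ll - trace[-1][1]) > 1e-3:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations "
            f"(last delta loglik {ll - trace[-1][1]:.3e})",
            trace,
        )

    # final quantities on the original scale
    cf, cfx, ViX, beta, Py = aux
    blups = {}
    for k, t in enumerate(terms):
        u = theta[k] * (t.C_pred @ Py) * sd
        blups[t.name] = pd.Series(u, index=t.pred_ids)

    # AI covariance of the variance parameters (original scale)
    try:
        ai_cov = np.linalg.inv(AI) * sd**4
    except np.linalg.LinAlgError:
        ai_cov = np.full((n_par, n_par), np.nan)

    return RemlResult(
        theta=theta * sd**2,
        param_names=names,
        loglik=ll - (n - p) * np.log(sd),
        beta=beta * sd,
        blups=blups,
        ai_cov=ai_cov,
        converged=converged,
        n_iter=len(trace),
        n_obs=n,
        rank_X=p,
        trace=trace,
    )
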