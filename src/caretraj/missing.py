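"""Little's MCAR test and expectation-maximization imputation for the four
intake covariate scales, under a multivariate-normal working model.

Both routines share one EM engine that estimates the mean vector and
covariance matrix from incomplete data by iterating conditional
expectations over the distinct missingness patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["McarResult", "McarUndefinedError", "EmConvergenceWarning",
           "em_mvn", "em_impute", "little_mcar_test"]

_RIDGE = 1e-8


class McarUndefinedError(ValueError):
    """Raised when the data admit no MCAR test (a single missingness
    pattern gives zero degrees of freedom)."""


class EmConvergenceWarning(UserWarning):
    """EM stopped at max_iter before meeting the tolerance; the last
    iterate is returned."""


@dataclass
class McarResult:
    chi2: float
    df: int
    p: float
    n_patterns: int


def _patterns(X):
    """Group row indices by missingness pattern (boolean observed mask)."""
    mask = ~np.isnan(X)
    uniq, inverse = np.unique(mask, axis=0, return_inverse=True)
    return [(uniq[j].astype(bool), np.nonzero(inverse == j)[0])
            for j in range(len(uniq))]


def em_mvn(X, max_iter: int = 500, tol: float = 1e-8):
    """ML mean and covariance of incomplete data under multivariate
    normality, via EM. Returns (mu, sigma, n_iter, converged); sigma uses
    the ML divisor n."""
    X = np.asarray(X, float)
    n, p = X.shape
    observed_any = ~np.isnan(X)
    if (observed_any.sum(axis=0) < 2).any():
        raise ValueError("every variable needs >= 2 observed values")
    mu = np.nanmean(X, axis=0)
    filled = np.where(np.isnan(X), mu, X)
    sigma = np.cov(filled, rowvar=False, bias=True) + _RIDGE * np.eye(p)
    pats = _patterns(X)

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for obs, rows in pats:
            xo = X[np.ix_(rows, obs)]
            m = ~obs
            comp = np.empty((len(rows), p))
            comp[:, obs] = xo
            cond_cov = np.zeros((p, p))
            if m.any():
                if obs.any():
                    soo = sigma[np.ix_(obs, obs)]
                    smo = sigma[np.ix_(m, obs)]
                    beta = np.linalg.solve(soo, smo.T).T
                    comp[:, m] = mu[m] + (xo - mu[obs]) @ beta.T
                    cc = sigma[np.ix_(m, m)] - beta @ smo.T
                else:
                    comp[:, m] = mu[m]
                    cc = sigma[np.ix_(m, m)]
                cond_cov[np.ix_(m, m)] = cc
            if obs.any():
                ll += stats.multivariate_normal.logpdf(
                    xo, mean=mu[obs], cov=sigma[np.ix_(obs, obs)],
                    allow_singular=True).sum()
            sum_x += comp.sum(axis=0)
            sum_xx += comp.T @ comp + len(rows) * cond_cov
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu) + _RIDGE * np.eye(p)
        if ll - ll_prev < tol * max(abs(ll), 1.0):
            converged = True
            break
        ll_prev = ll
    if not converged:
        warnings.warn("EM did not converge within max_iter; returning the "
                      "last iterate", EmConvergenceWarning)
    return mu, sigma, it, converged


def em_impute(X, max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Replace missing cells by their conditional means given the row's
    observed variables under the EM-estimated (mu, sigma); observed cells
    are returned unchanged."""
    X = np.asarray(X, float)
    out = X.copy()
    if not np.isnan(X).any():
        return out
    mu, sigma, _, _ = em_mvn(X, max_iter=max_iter, tol=tol)
    for obs, rows in _patterns(X):
        m = ~obs
        if not m.any():
            continue
        if obs.any():
            beta = np.linalg.solve(sigma[np.ix_(obs, obs)],
                                   sigma[np.ix_(m, obs)].T).T
            out[np.ix_(rows, m)] = (mu[m]
                                    + (X[np.ix_(rows, obs)] - mu[obs])
                                    @ beta.T)
        else:
            out[np.ix_(rows, m)] = mu[m]
    return out


def little_mcar_test(X, max_iter: int = 500, tol: float = 1e-8) -> McarResult:
    """Little's chi-square test of missing completely at random.

    With EM estimates (mu, sigma), each missingness pattern j contributes
    n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j), restricted to the
    pattern's observed variables; df = sum_j p_j - p. A small chi-square
    (large p) is consistent with MCAR.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    pats = [(obs, rows) for obs, rows in _patterns(X) if obs.any()]
    if len(pats) < 2:
        raise McarUndefinedError(
            "only one missingness pattern: MCAR test has 0 df")
    mu, sigma, _, _ = em_mvn(X, max_iter=max_iter, tol=tol)
    chi2 = 0.0
    df = -p
    for obs, rows in pats:
        ybar = X[np.ix_(rows, obs)].mean(axis=0)
        diff = ybar - mu[obs]
        soo = sigma[np.ix_(obs, obs)] + _RIDGE * np.eye(obs.sum())
        chi2 += len(rows) * float(diff @ np.linalg.solve(soo, diff))
        df += int(obs.sum())
    if df <= 0:
        raise McarUndefinedError("non-positive degrees of freedom")
    return McarResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)),
                      n_patterns=len(pats))
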