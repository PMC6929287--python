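"""Binary latent class analysis of 48-month visit trajectories.

Finite mixture of independent Bernoulli profiles: child i belongs to latent
class k with probability pi_k, and conditional on class membership has a
visit in month j with probability theta_kj, independently across months.
Parameters are estimated by expectation-maximization from multiple random
starts, with a continued-EM polish phase at a tightened tolerance in place
of a proprietary Newton-Raphson finisher (the maximizer, not the algorithm,
defines the result).

Model selection follows an a-priori rule: the number of classes grows while
the average relative improvement across AIC, BIC and CAIC is at least 2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "LCAModel", "LCAFit", "SelectionTrace",
    "em_fit", "grouped_fit", "fit_indices", "entropy",
    "select_num_classes", "choose_from_improvements", "modal_assignment",
    "bootstrap_gof",
    "loglik_brute_force", "sample_from_model",
]

THETA_FLOOR = 1e-6


@dataclass
class LCAModel:
    pi: np.ndarray          # class weights, canonical (descending) order
    theta: np.ndarray       # K x J conditional visit probabilities
    group_pi: np.ndarray | None = None   # G x K, grouped variant only

    @property
    def K(self) -> int:
        return self.theta.shape[0]


@dataclass
class LCAFit:
    model: LCAModel
    loglik: float
    n_params: int
    aic: float
    bic: float
    caic: float
    posteriors: np.ndarray  # n x K
    entropy: float
    n_starts_used: int
    converged: bool
    best_start_seed: int
    loglik_trace: np.ndarray = field(repr=False, default=None)


@dataclass
class SelectionTrace:
    table: list[dict]       # per-K: K, loglik, aic, bic, caic, improvement
    chosen_k: int
    fits: dict              # K -> LCAFit


def fit_indices(loglik: float, n_params: int, n: int
                ) -> tuple[float, float, float]:
    """(AIC, BIC, CAIC) = -2l + p*c with c = 2, ln n, ln n + 1."""
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n)
    caic = -2.0 * loglik + n_params * (np.log(n) + 1.0)
    return aic, bic, caic


def entropy(posteriors: np.ndarray) -> float:
    """Relative entropy of the posterior classification, in [0, 1].

    1 - (average Shannon uncertainty of the posterior rows) / ln K;
    1 means perfectly separated classes, 0 means uniform posteriors.
    K = 1 is defined as 1 (classification is certain).
    """
    p = np.asarray(posteriors, float)
    n, K = p.shape
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


def _log_components(X, theta, log_weights):
    """n x K matrix log pi_k + sum_j log Bernoulli(x_ij; theta_kj)."""
    lt = np.log(theta)
    l1t = np.log1p(-theta)
    return X @ (lt - l1t).T + l1t.sum(axis=1) + log_weights


def _em_once(X, K, rng, groups, n_groups, max_em_iter, polish_iter,
             tol, polish_tol):
    n, J = X.shape
    theta = rng.uniform(0.25, 0.75, size=(K, J))
    if groups is None:
        log_pi = np.log(np.full(K, 1.0 / K))
    else:
        log_pi = np.log(np.full((n_groups, K), 1.0 / K))[groups]
    trace = []
    ll_prev = -np.inf
    converged = False
    phases = ((max_em_iter, tol), (polish_iter, polish_tol))
    for phase, (n_iter, phase_tol) in enumerate(phases):
        for _ in range(n_iter):
            logc = _log_components(X, theta, log_pi)
            lse = logsumexp(logc, axis=1)
            ll = float(lse.sum())
            trace.append(ll)
            resp = np.exp(logc - lse[:, None])
            nk = resp.sum(axis=0)
            if groups is None:
                log_pi = np.log(np.maximum(nk / n, 1e-300))
            else:
                gp = np.zeros((n_groups, K))
                np.add.at(gp, groups, resp)
                gp /= gp.sum(axis=1, keepdims=True)
                log_pi = np.log(np.maximum(gp, 1e-300))[groups]
            theta = np.clip(resp.T @ X / np.maximum(nk, 1e-300)[:, None],
                            THETA_FLOOR, 1.0 - THETA_FLOOR)
            if ll - ll_prev < phase_tol * max(abs(ll), 1.0):
                if phase == 1:
                    converged = True
                    break
                ll_prev = ll
                break
            ll_prev = ll
        else:
            if phase == 1:
                converged = False
    # final evaluation at the parameters of the last M-step, so the
    # returned loglik corresponds exactly to (pi, theta)
    logc = _log_components(X, theta, log_pi)
    lse = logsumexp(logc, axis=1)
    ll = float(lse.sum())
    resp = np.exp(logc - lse[:, None])
    if groups is None:
        pi = np.exp(log_pi)
        group_pi = None
    else:
        group_pi = np.exp(log_pi[np.unique(groups, return_index=True)[1]])
        pi = resp.mean(axis=0)
    return pi, theta, group_pi, resp, ll, np.array(trace), converged


def em_fit(X: np.ndarray, K: int, n_starts: int = 10,
           max_em_iter: int = 250, polish_iter: int = 50,
           tol: float = 1e-7, polish_tol: float = 1e-8,
           seed: int = 0, groups=None) -> LCAFit:
    """Fit a K-class Bernoulli mixture by multi-start EM.

    The best of ``n_starts`` runs (by final log-likelihood) is returned,
    with classes relabelled in canonical order of descending class weight.
    ``groups`` (optional per-row group ids) switches to the grouped variant
    with group-specific class weights and shared item probabilities.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D indicator matrix")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("X must be binary")
    n, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("more classes than observations")

    n_groups = None
    if groups is not None:
        groups = np.asarray(groups)
        codes, groups = np.unique(groups, return_inverse=True)
        n_groups = len(codes)
        if n_groups < 1:
            raise ValueError("empty groups")
        if np.bincount(groups).min() < K:
            raise ValueError("every group needs at least K members")

    best = None
    for s in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
        res = _em_once(X, K, rng, groups, n_groups, max_em_iter,
                       polish_iter, tol, polish_tol)
        if best is None or res[4] > best[1][4]:
            best = (s, res)
    s, (pi, theta, group_pi, resp, ll, trace, converged) = best

    order = np.argsort(-pi, kind="stable")
    pi, theta, resp = pi[order], theta[order], resp[:, order]
    if group_pi is not None:
        group_pi = group_pi[:, order]

    if group_pi is None:
        n_params = (K - 1) + K * J
    else:
        n_params = n_groups * (K - 1) + K * J
    aic, bic, caic = fit_indices(ll, n_params, n)
    model = LCAModel(pi=pi, theta=theta, group_pi=group_pi)
    return LCAFit(model=model, loglik=ll, n_params=n_params,
                  aic=aic, bic=bic, caic=caic, posteriors=resp,
                  entropy=entropy(resp), n_starts_used=n_starts,
                  converged=converged, best_start_seed=s, loglik_trace=trace)


def grouped_fit(X, groups, K, **kwargs) -> LCAFit:
    """Grouped-weights variant: class weights vary by group (cohort or
    agency), item probabilities are shared. Comparing its BIC against the
    plain fit checks whether group structure adds anything."""
    return em_fit(X, K, groups=groups, **kwargs)


def choose_from_improvements(ks, improvements, threshold: float = 0.02,
                             converged=None) -> int:
    """Apply the average-improvement stopping rule to a precomputed scan.

    ``improvements[i]`` is the mean relative improvement of K = ks[i+1]
    over ks[i]; the chosen K is the largest one reached before the first
    improvement below ``threshold`` (or non-converged fit).
    """
    chosen = ks[0]
    ok = [True] * len(ks) if converged is None else list(converged)
    for i, imp in enumerate(improvements):
        if imp >= threshold and ok[i + 1]:
            chosen = ks[i + 1]
        else:
            break
    return chosen


def select_num_classes(X, k_range=range(2, 11), threshold: float = 0.02,
                       seed: int = 0, **em_kwargs) -> SelectionTrace:
    """Scan K upward; keep growing while the mean relative improvement of
    (AIC, BIC, CAIC) over the previous K is at least ``threshold``; the
    chosen K is the last one before the first failure."""
    ks = list(k_range)
    if ks != sorted(ks):
        raise ValueError("k_range must be ascending")
    table = []
    fits = {}
    improvements = []
    converged = []
    prev = None
    for K in ks:
        fit = em_fit(X, K, seed=seed, **em_kwargs)
        fits[K] = fit
        idx = np.array([fit.aic, fit.bic, fit.caic])
        if (idx <= 0).any():
            raise ValueError("non-positive fit index: relative-improvement "
                             "rule undefined")
        improvement = None
        if prev is not None:
            improvement = float(np.mean((prev - idx) / prev))
            improvements.append(improvement)
        converged.append(fit.converged)
        table.append({"K": K, "loglik": fit.loglik, "aic": fit.aic,
                      "bic": fit.bic, "caic": fit.caic,
                      "avg_improvement": improvement,
                      "converged": fit.converged})
        prev = idx
    chosen = choose_from_improvements(ks, improvements, threshold, converged)
    for row in table:
        row["chosen"] = row["K"] == chosen
    return SelectionTrace(table=table, chosen_k=chosen, fits=fits)


def modal_assignment(posteriors: np.ndarray) -> np.ndarray:
    """Most-probable class per row; ties break to the lowest class index."""
    return np.argmax(np.asarray(posteriors), axis=1)


def loglik_brute_force(X, pi, theta) -> float:
    """Direct per-child mixture density sum (oracle for small instances)."""
    total = 0.0
    for x in np.asarray(X, float):
        like = sum(
            pi[k] * np.prod(theta[k] ** x * (1 - theta[k]) ** (1 - x))
            for k in range(len(pi)))
        total += np.log(like)
    return float(total)


def sample_from_model(model: LCAModel, n: int, rng) -> np.ndarray:
    """Draw an n x J binary matrix from a fitted mixture."""
    z = rng.choice(model.K, size=n, p=model.pi / model.pi.sum())
    return (rng.random((n, model.theta.shape[1]))
            < model.theta[z]).astype(float)


def _saturated_loglik(X) -> float:
    _, counts = np.unique(np.asarray(X, int), axis=0, return_counts=True)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


def bootstrap_gof(fit: LCAFit, X, n_boot: int = 500, seed: int = 0,
                  n_starts: int = 2, **em_kwargs) -> float:
    """Parametric bootstrap p-value of the likelihood-ratio goodness-of-fit
    statistic G2 = 2(l_saturated - l_model).

    Simulates ``n_boot`` datasets from the fitted model, refits K classes to
    each, and reports the fraction of simulated G2 at or above the observed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(X, float)
    n = X.shape[0]
    g2_obs = 2.0 * (_saturated_loglik(X) - fit.loglik)
    rng = np.random.default_rng(seed)
    K = fit.model.K
    exceed = 0
    for b in range(n_boot):
        Xb = sample_from_model(fit.model, n, rng)
        fb = em_fit(Xb, K, n_starts=n_starts,
                    seed=int(rng.integers(2**31)), **em_kwargs)
        g2_b = 2.0 * (_saturated_loglik(Xb) - fb.loglik)
        if g2_b >= g2_obs:
            exceed += 1
    return exceed / n_boot
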