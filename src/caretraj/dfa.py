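"""Canonical discriminant function analysis.

Linear discriminant functions are the eigenvectors of W^{-1}B (within- and
between-groups SSCP matrices), scaled so canonical scores have pooled
within-group variance 1. Reported alongside: standardized coefficients
(raw times pooled within-group SDs), structure coefficients (pooled
within-groups correlations between predictors and canonical scores), group
centroids, Bartlett's sequential Wilks-lambda chi-square tests, and
prior-weighted Gaussian classification with jackknife (leave-one-out)
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = ["DFAModel", "DFAReport", "fit", "wilks_sequence",
           "classify", "loo_cv", "report"]


@dataclass
class DFAModel:
    eigenvalues: np.ndarray              # descending, length s
    raw_coefficients: np.ndarray         # p x s
    standardized_coefficients: np.ndarray
    structure_coefficients: np.ndarray
    centroids: np.ndarray                # g x s, grand-mean-centred scores
    priors: np.ndarray
    pooled_within_cov: np.ndarray        # divisor n - g
    class_means: np.ndarray              # g x p
    class_counts: np.ndarray
    classes: np.ndarray
    grand_mean: np.ndarray
    n: int
    p: int
    g: int

    @property
    def s(self) -> int:
        return len(self.eigenvalues)

    def scores(self, X) -> np.ndarray:
        """Canonical scores (grand-mean-centred)."""
        return (np.asarray(X, float) - self.grand_mean) @ self.raw_coefficients

    def percent_variance(self) -> np.ndarray:
        lam = self.eigenvalues
        return lam / lam.sum() * 100.0 if lam.sum() > 0 else lam * 0.0


@dataclass
class DFAReport:
    wilks: list[dict]             # per functions-removed m: lambda, chi2, df, p
    percent_variance: np.ndarray
    classification_table: np.ndarray   # g x g, rows true, cols predicted
    resubstitution_accuracy: float     # %
    loo_accuracy: float                # %


def _resolve_priors(priors, counts):
    n = counts.sum()
    if isinstance(priors, str):
        if priors != "proportional":
            raise ValueError("priors must be 'proportional' or a vector")
        return counts / n
    pr = np.asarray(priors, float)
    if abs(pr.sum() - 1.0) > 1e-9 or len(pr) != len(counts):
        raise ValueError("priors must sum to 1, one per group")
    return pr


def fit(X, labels, priors="proportional") -> DFAModel:
    """Fit the canonical discriminant model; see the module docstring."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    n, p = X.shape
    g = len(classes)
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 cases")
    if n <= p + g:
        raise ValueError("too few cases for the predictor/group count")
    means = np.vstack([X[y == k].mean(axis=0) for k in range(g)])
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    for k in range(g):
        d = X[y == k] - means[k]
        W += d.T @ d
    dm = means - grand
    B = (dm.T * counts) @ dm
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular within-groups matrix: predictors are collinear")
    s = min(p, g - 1)
    # generalized symmetric problem B v = lambda W v
    lam, vec = linalg.eigh(B, W)
    order = np.argsort(lam)[::-1][:s]
    lam = np.maximum(lam[order], 0.0)
    A = vec[:, order]
    Sw = W / (n - g)
    # scale so canonical scores have pooled within-group variance 1
    scale = np.sqrt(np.einsum("ps,pq,qs->s", A, Sw, A))
    A = A / scale
    sd_w = np.sqrt(np.diag(Sw))
    std = A * sd_w[:, None]
    # deterministic sign: largest-magnitude standardized loading positive
    signs = np.sign(std[np.argmax(np.abs(std), axis=0), np.arange(s)])
    signs[signs == 0] = 1.0
    A, std = A * signs, std * signs
    structure = (Sw @ A) / sd_w[:, None]
    centroids = (means - grand) @ A
    return DFAModel(
        eigenvalues=lam, raw_coefficients=A, standardized_coefficients=std,
        structure_coefficients=structure, centroids=centroids,
        priors=_resolve_priors(priors, counts), pooled_within_cov=Sw,
        class_means=means, class_counts=counts, classes=classes,
        grand_mean=grand, n=n, p=p, g=g)


def wilks_sequence(model: DFAModel, n: int | None = None) -> list[dict]:
    """Bartlett chi-square tests of the functions remaining after removing
    the first m, for m = 0..s-1.

    Lambda_m = prod_{i>m} 1/(1+lambda_i); chi2 = -(n - 1 - (p+g)/2) ln
    Lambda_m; df = (p-m)(g-1-m).
    """
    n = model.n if n is None else n
    p, g = model.p, model.g
    out = []
    for m in range(model.s):
        lam_rest = model.eigenvalues[m:]
        wl = float(np.prod(1.0 / (1.0 + lam_rest)))
        chi2 = -(n - 1 - (p + g) / 2.0) * np.log(wl)
        df = (p - m) * (g - 1 - m)
        out.append({"functions_removed": m, "wilks_lambda": wl,
                    "chi2": float(chi2), "df": int(df),
                    "p": float(stats.chi2.sf(chi2, df))})
    return out


def _discriminant_scores(model: DFAModel, X) -> np.ndarray:
    """Equal-covariance Gaussian log-posterior scores (up to a constant)."""
    X = np.asarray(X, float)
    Swinv_mu = np.linalg.solve(model.pooled_within_cov, model.class_means.T)
    lin = X @ Swinv_mu
    const = -0.5 * np.einsum("kp,pk->k", model.class_means, Swinv_mu) \
        + np.log(model.priors)
    return lin + const


def classify(model: DFAModel, X) -> np.ndarray:
    """Assign each case to the class with the largest prior-weighted
    discriminant score (smallest Mahalanobis distance to centroid minus
    2 ln prior)."""
    return model.classes[np.argmax(_discriminant_scores(model, X), axis=1)]


def loo_cv(X, labels, priors="proportional") -> float:
    """Jackknife accuracy (%): refit excluding each case, classify it."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    correct = 0
    idx = np.arange(len(X))
    for i in idx:
        keep = idx != i
        m = fit(X[keep], labels[keep], priors=priors)
        if classify(m, X[i:i + 1])[0] == labels[i]:
            correct += 1
    return correct / len(X) * 100.0


def report(X, labels, priors="proportional", loo: bool = True) -> DFAReport:
    """Fit, test, classify and cross-validate in one pass."""
    model = fit(X, labels, priors=priors)
    pred = classify(model, X)
    g = model.g
    table = np.zeros((g, g), dtype=int)
    lab_idx = {c: k for k, c in enumerate(model.classes)}
    for t, q in zip(labels, pred):
        table[lab_idx[t], lab_idx[q]] += 1
    resub = np.trace(table) / table.sum() * 100.0
    loo_acc = loo_cv(X, labels, priors=priors) if loo else np.nan
    return DFAReport(wilks=wilks_sequence(model),
                     percent_variance=model.percent_variance(),
                     classification_table=table,
                     resubstitution_accuracy=float(resub),
                     loo_accuracy=float(loo_acc))
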