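"""Phylogenetic logistic regression (evolving-threshold / GEE formulation).

A binary response is modeled with logistic mean structure; phylogenetic
dependence enters through a working correlation exp(-alpha * D) on the
patristic distance matrix, in the spirit of the Ives-Garland
evolving-threshold model. The signal parameter alpha is profiled on a
Gaussian pseudo-likelihood of the Pearson residuals; in the
alpha -> infinity (no-signal) limit the estimating equations reduce
exactly to ordinary logistic ML.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from fishor.pcm.pgls import ComparativeFit
from fishor.treeutils import patristic_matrix

_RIDGE = 1e-8


def _logit_mu(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def _gee_fit(y, X, R_inv, max_iter=100, ridge=0.0):
    """Solve the GEE score equations with working correlation R.

    With D = diag(v) X (v = mu(1-mu)) and working covariance
    A^(1/2) R A^(1/2), the score is (X sqrt(v))' R^-1 e with
    e = (y-mu)/sqrt(v); for R = I this is exactly the logistic ML score.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = _logit_mu(X @ beta)
        w = np.sqrt(np.maximum(mu * (1 - mu), 1e-12))
        Xw = X * w[:, None]
        e = (y - mu) / w
        A = Xw.T @ (R_inv @ Xw) + ridge * np.eye(X.shape[1])
        g = Xw.T @ (R_inv @ e) - ridge * beta
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            return beta, True
    return beta, False


def _model_se(y, X, beta, R_inv):
    """Model-based standard errors with estimated dispersion."""
    mu = _logit_mu(X @ beta)
    w = np.sqrt(np.maximum(mu * (1 - mu), 1e-12))
    Xw = X * w[:, None]
    e = (y - mu) / w
    bread_inv = np.linalg.inv(Xw.T @ (R_inv @ Xw))
    phi = float(e @ R_inv @ e) / max(len(y) - X.shape[1], 1)
    return np.sqrt(np.maximum(np.diag(bread_inv) * phi, 0))


def phylo_logistic(tree, response: dict, predictors: dict[str, dict],
                   alpha: float | None = None) -> ComparativeFit:
    """Phylogenetic logistic regression of a binary response.

    ``alpha`` fixes the dependence parameter (None = profile it; large
    values recover ordinary logistic regression). A constant predictor is
    NaN-marked and an intercept-only fit returned; complete separation
    triggers a flagged ridge-penalized fallback.
    """
    taxa = sorted(set(response) & set.intersection(*(set(v) for v in predictors.values())))
    if len(taxa) < len(predictors) + 2:
        raise ValueError("not enough complete cases")
    y = np.array([float(response[t]) for t in taxa])
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    names = ["intercept"] + list(predictors)
    cols = [np.ones(len(taxa))]
    flags = []
    dropped = []
    for p in predictors:
        col = np.array([float(predictors[p][t]) for t in taxa])
        if np.allclose(col.std(), 0):
            dropped.append(p)
            flags.append(f"constant predictor {p}: slope undefined")
        else:
            cols.append(col)
    X = np.column_stack(cols)
    used_names = ["intercept"] + [p for p in predictors if p not in dropped]

    D, _ = patristic_matrix(tree, taxa)
    depth = float(D.max()) or 1.0
    n = len(y)

    def r_inv_of(a):
        R = np.exp(-a * D)
        np.fill_diagonal(R, 1.0)
        return np.linalg.inv(R + _RIDGE * np.eye(n)), R

    def pseudo_neg_loglik(a):
        R_inv, R = r_inv_of(a)
        beta, ok = _gee_fit(y, X, R_inv)
        if not ok:
            return 1e12
        mu = _logit_mu(X @ beta)
        w = np.sqrt(np.maximum(mu * (1 - mu), 1e-12))
        e = (y - mu) / w
        sign, logdet = np.linalg.slogdet(R + _RIDGE * np.eye(n))
        phi = float(e @ R_inv @ e) / n
        if phi <= 0:
            return 1e12
        return 0.5 * (n * math.log(phi) + logdet)

    if alpha is None:
        res = minimize_scalar(pseudo_neg_loglik,
                              bounds=(0.05 / depth, 100.0 / depth),
                              method="bounded", options={"xatol": 1e-6})
        alpha_hat = float(res.x)
    else:
        alpha_hat = float(alpha)
    R_inv, _R = r_inv_of(alpha_hat)
    beta, converged = _gee_fit(y, X, R_inv)
    mu = _logit_mu(X @ beta)
    separated = np.all((mu > 0.5) == (y > 0.5)) and (np.min(np.abs(mu - 0.5)) > 0.49)
    if not converged or separated or np.max(np.abs(beta)) > 30:
        flags.append("complete separation: ridge-penalized fallback")
        beta, _ = _gee_fit(y, X, R_inv, ridge=1e-3)
    se = _model_se(y, X, beta, R_inv)
    z = beta / np.where(se > 0, se, np.nan)
    pvals = 2 * norm.sf(np.abs(z))

    coef = dict(zip(used_names, map(float, beta)))
    ses = dict(zip(used_names, map(float, se)))
    zs = dict(zip(used_names, map(float, z)))
    ps = dict(zip(used_names, map(float, pvals)))
    for p in dropped:
        coef[p] = math.nan
        ses[p] = math.nan
        zs[p] = math.nan
        ps[p] = math.nan
    first = names[1] if len(names) > 1 else None
    if first and np.isfinite(zs.get(first, math.nan)):
        z1 = zs[first]
        r = math.copysign(math.sqrt(z1 * z1 / (z1 * z1 + n - X.shape[1])), z1)
    else:
        r = math.nan
    return ComparativeFit(model="logistic", coef=coef, se=ses, t_stats=zs,
                          p_values=ps, r=r, log_likelihood=math.nan,
                          aic=math.nan, n=n,
                          structure={"alpha": alpha_hat}, flags=flags)
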