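"""Phylogenetic generalized least squares under BM, OU or lambda covariance."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from fishor.pcm.signal import lambda_cov
from fishor.treeutils import patristic_matrix, vcv_matrix


@dataclass
class ComparativeFit:
    model: str
    coef: dict[str, float]
    se: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    r: float                      # sign-carrying correlation-scale effect size
    log_likelihood: float
    aic: float
    n: int
    structure: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """ML GLS: returns (logL, beta, cov_beta_unit, sigma2)."""
    n = len(y)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -math.inf, None, None, None
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    A = XtVi @ X
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    sigma2 = float(r @ Vi @ r) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    logL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return logL, beta, np.linalg.inv(A), sigma2


def _check_design(X: np.ndarray, names: list[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of offending columns by greedy scan
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                bad.append(names[j])
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def pgls(tree, response: dict, predictors: dict[str, dict], model: str = "lambda",
         fixed_lambda: float | None = None) -> ComparativeFit:
    """Phylogenetic linear regression.

    ``response`` maps tip -> value; ``predictors`` maps name -> {tip ->
    value}. ``model`` is BM, OU or lambda; the structure parameter is
    ML-estimated jointly (or fixed via ``fixed_lambda``). The effect size
    r = sign(t) * sqrt(t^2 / (t^2 + df)) is reported for the first
    predictor.
    """
    model = model.lower()
    if model not in ("bm", "ou", "lambda"):
        raise ValueError(f"unknown PGLS model {model!r}")
    taxa = sorted(set(response) & set.intersection(*(set(v) for v in predictors.values()))
                  ) if predictors else sorted(response)
    k = len(predictors)
    if len(taxa) < k + 2:
        raise ValueError("not enough complete cases")
    y = np.array([float(response[t]) for t in taxa])
    names = ["intercept"] + list(predictors)
    X = np.column_stack([np.ones(len(taxa))]
                        + [[float(predictors[p][t]) for t in taxa] for p in predictors])
    _check_design(X, names)
    C, _ = vcv_matrix(tree, taxa)

    structure: dict[str, float] = {}
    n_struct = 0
    if model == "bm":
        V = C
        logL, beta, covu, sigma2 = _gls_fit(y, X, V)
    elif model == "lambda":
        if fixed_lambda is not None:
            lam = float(fixed_lambda)
        else:
            res = minimize_scalar(lambda l: -_gls_fit(y, X, lambda_cov(C, l))[0],
                                  bounds=(0.0, 1.0), method="bounded",
                                  options={"xatol": 1e-8})
            cands = [(-_gls_fit(y, X, lambda_cov(C, l))[0], l) for l in (0.0, 1.0)]
            cands.append((res.fun, float(res.x)))
            _, lam = min(cands, key=lambda kv: kv[0])
            n_struct = 1
        structure["lambda"] = lam
        V = lambda_cov(C, lam)
        logL, beta, covu, sigma2 = _gls_fit(y, X, V)
    else:  # OU with stationary covariance on patristic distances
        D, _ = patristic_matrix(tree, taxa)
        depth = float(np.max(np.diag(C))) or 1.0

        def v_of(alpha):
            return np.exp(-alpha * D)

        res = minimize_scalar(lambda a: -_gls_fit(y, X, v_of(a))[0],
                              bounds=(1e-9, 50.0 / depth), method="bounded",
                              options={"xatol": 1e-10})
        alpha = float(res.x)
        structure["alpha"] = alpha
        n_struct = 1
        V = v_of(alpha)
        logL, beta, covu, sigma2 = _gls_fit(y, X, V)

    n = len(y)
    df = n - X.shape[1]
    se = np.sqrt(np.maximum(np.diag(covu) * sigma2 * n / max(df, 1), 0))
    tstats = beta / np.where(se > 0, se, np.nan)
    pvals = 2 * t_dist.sf(np.abs(tstats), df)
    n_params = X.shape[1] + 1 + n_struct
    aic = 2 * n_params - 2 * logL
    if k >= 1:
        t1 = tstats[1]
        r = math.copysign(math.sqrt(t1 * t1 / (t1 * t1 + df)), t1) if np.isfinite(t1) else math.nan
    else:
        r = math.nan
    return ComparativeFit(model=model,
                          coef=dict(zip(names, map(float, beta))),
                          se=dict(zip(names, map(float, se))),
                          t_stats=dict(zip(names, map(float, tstats))),
                          p_values=dict(zip(names, map(float, pvals))),
                          r=r, log_likelihood=logL, aic=aic, n=n,
                          structure=structure)
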