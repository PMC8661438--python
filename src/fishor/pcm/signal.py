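"""Pagel's lambda: phylogenetic signal of a continuous trait."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from fishor.treeutils import vcv_matrix


@dataclass
class LambdaFit:
    lam: float
    log_likelihood: float
    logL_lambda0: float
    p_value: float
    mu: float
    sigma2: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.lam)


def _profile_loglik(y: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """ML profile of (mu, sigma2) under N(mu*1, sigma2*V)."""
    n = len(y)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -math.inf, math.nan, math.nan
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = float(one @ Vi @ y) / float(one @ Vi @ one)
    r = y - mu
    sigma2 = float(r @ Vi @ r) / n
    if sigma2 <= 0:
        return -math.inf, mu, sigma2
    logL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return logL, mu, sigma2


def lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariance entries by lambda."""
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def pagel_lambda(tree, trait: dict) -> LambdaFit:
    """ML estimate of Pagel's lambda with an LRT against lambda = 0.

    ``trait`` maps tip label -> value; at least 4 tips required. On a star
    tree (or zero trait variance) the likelihood is flat in lambda and the
    estimate is NaN-marked.
    """
    taxa = sorted(trait)
    if len(taxa) < 4:
        raise ValueError("need at least 4 tips with data")
    C, taxa = vcv_matrix(tree, taxa)
    y = np.array([float(trait[t]) for t in taxa])
    if np.allclose(y.std(), 0):
        return LambdaFit(math.nan, math.nan, math.nan, math.nan, math.nan, math.nan)
    offdiag = C - np.diag(np.diag(C))
    if np.allclose(offdiag, 0):
        logL0, mu, s2 = _profile_loglik(y, C)
        return LambdaFit(math.nan, logL0, logL0, 1.0, mu, s2)

    def neg(lam):
        return -_profile_loglik(y, lambda_cov(C, lam))[0]

    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    # guard the boundaries explicitly: the optimum is often at 0 or 1
    candidates = [(neg(0.0), 0.0), (neg(1.0), 1.0), (res.fun, float(res.x))]
    fun, lam = min(candidates, key=lambda kv: kv[0])
    logL, mu, sigma2 = _profile_loglik(y, lambda_cov(C, lam))
    logL0, _, _ = _profile_loglik(y, lambda_cov(C, 0.0))
    lrt = max(0.0, 2.0 * (logL - logL0))
    p = float(chi2.sf(lrt, df=1))
    return LambdaFit(lam=lam, log_likelihood=logL, logL_lambda0=logL0,
                     p_value=p, mu=mu, sigma2=sigma2)
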