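"""Fast univariate logistic p-values for the cutoff scan.

The cutoff search fits one logistic regression per candidate threshold
per block, which makes it the hot loop of the simulation harness.  Two
exact shortcuts keep it cheap:

* a two-valued predictor saturates the univariate logistic model, so
  the MLE is the 2x2-table log odds ratio with the standard Woolf
  standard error -- identical to the iterated fit;
* otherwise a small Newton-Raphson on the standardized predictor (the
  Wald z and p are invariant to affine rescaling of the predictor).

Complete or quasi-complete separation (diverging slope) falls back to
the likelihood-ratio test and is flagged.  Agreement with statsmodels
is pinned by tests.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

__all__ = ["LogitScan", "logit_pvalue"]

_MAX_ABS_SLOPE = 15.0   # on the standardized scale; beyond this = separation


class LogitScan(NamedTuple):
    beta: float
    se: float
    pvalue: float
    separated: bool
    loglik: float       # at the fit (or its capped limit under separation)
    loglik_null: float


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _null_loglik(y: np.ndarray) -> float:
    n, k = len(y), int(y.sum())
    if k in (0, n):
        return 0.0
    p = k / n
    return k * np.log(p) + (n - k) * np.log(1 - p)


def _bernoulli_ll(k: float, m: float) -> float:
    if m == 0 or k == 0 or k == m:
        return 0.0
    p = k / m
    return k * np.log(p) + (m - k) * np.log(1 - p)


def _binary_path(s: np.ndarray, y: np.ndarray) -> LogitScan:
    lo, hi = np.min(s), np.max(s)
    pos = s == hi
    a = float(np.sum(pos & (y == 1)))
    b = float(np.sum(pos & (y == 0)))
    c = float(np.sum(~pos & (y == 1)))
    d = float(np.sum(~pos & (y == 0)))
    scale = hi - lo
    ll0 = _null_loglik(y)
    # the univariate logistic model is saturated for a two-valued
    # predictor, so its maximised ll splits by predictor level
    ll1 = _bernoulli_ll(a, a + b) + _bernoulli_ll(c, c + d)
    if min(a, b, c, d) > 0:
        beta = np.log(a * d / (b * c)) / scale
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d) / scale
        z = beta / se
        return LogitScan(beta, se, 2 * stats.norm.sf(abs(z)), False, ll1, ll0)
    # zero cell: slope diverges -> likelihood-ratio test (ll1 is the limit)
    g = 2 * (ll1 - ll0)
    return LogitScan(np.inf if (a * d > b * c) else -np.inf, np.inf,
                     float(stats.chi2.sf(max(g, 0.0), 1)), True, ll1, ll0)


def logit_pvalue(S: np.ndarray, y: np.ndarray) -> Optional[LogitScan]:
    """Wald test of the slope in logit P(y=1) = b0 + b1*S.

    Returns ``None`` for a constant predictor.  On separation the
    p-value is the likelihood-ratio test and ``separated`` is set.
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float)
    uniq = np.unique(S)
    if len(uniq) < 2:
        return None
    if len(uniq) == 2:
        return _binary_path(S, y)

    mu_s, sd_s = S.mean(), S.std()
    s = (S - mu_s) / sd_s
    n = len(y)
    X = np.column_stack([np.ones(n), s])
    beta = np.array([np.log(y.mean() / (1 - y.mean())), 0.0])
    ll = _loglik(X @ beta, y)
    converged = False
    H = None
    for _ in range(40):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee likelihood ascent
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _loglik(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta, ll = beta + t * step, ll_new
        if np.max(np.abs(grad)) < 1e-9:
            converged = True
            break
    ll0 = _null_loglik(y)
    if not converged or abs(beta[1]) > _MAX_ABS_SLOPE:
        lrt = 2 * (ll - ll0)
        return LogitScan(np.sign(beta[1]) * np.inf, np.inf,
                         float(stats.chi2.sf(max(lrt, 0.0), 1)), True, ll, ll0)
    cov = np.linalg.inv(H)
    se_std = np.sqrt(cov[1, 1])
    z = beta[1] / se_std
    return LogitScan(beta[1] / sd_s, se_std / sd_s,
                     2 * stats.norm.sf(abs(z)), False, ll, ll0)
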