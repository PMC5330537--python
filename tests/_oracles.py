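"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the scoring/flagging rules and
first-principles statistics, in plain Python, deliberately not sharing any
code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_score(v1: int, s1: int, log_base: float = 2.0, pseudocount: float = 0.0):
    """Log ratio of V1 to S1 counts; None where a zero count makes it undefined."""
    v = v1 + pseudocount
    s = s1 + pseudocount
    if v <= 0 or s <= 0:
        return None
    return math.log(v / s, log_base)


def oracle_flag(v1: int, s1: int, control: int, threshold: float = 3.0,
                log_base: float = 2.0) -> int:
    """0 when data is absent in any condition, else 1 iff |score| >= threshold."""
    if v1 == 0 or s1 == 0 or control == 0:
        return 0
    return 1 if abs(oracle_score(v1, s1, log_base)) >= threshold else 0


def oracle_call(v1: int, s1: int, control: int, threshold: float = 3.0):
    """'paired' / 'single' on flagged positions by the sign of the score."""
    if oracle_flag(v1, s1, control, threshold) == 0:
        return "unknown"
    return "paired" if oracle_score(v1, s1) > 0 else "single"


def oracle_retained(flags: list[int], retention: float = 0.80) -> bool:
    return sum(flags) / len(flags) >= retention


def oracle_pearson(x, y):
    """Two-pass covariance formula plus the t transform on n-2 df."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    from scipy.stats import t as tdist

    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * tdist.sf(abs(t), n - 2)


def newton_logit(y, x, tol: float = 1e-12, maxiter: int = 200):
    """Newton-Raphson maximum likelihood for logistic regression with one
    predictor; returns (beta, covariance)."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(x, dtype=float)])
    beta = np.zeros(2)
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration:
    sum the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(n, k):
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    def log_p(a_):
        return (
            log_comb(r1, a_)
            + log_comb(r2, c1 - a_)
            - log_comb(n, c1)
        )

    lp_obs = log_p(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = log_p(a_)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)
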