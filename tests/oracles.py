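"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the stratifier
oracle applies the prose rounding rules instead of interval tables, the
c-index oracle enumerates pairs with explicit loops, and the Cox oracle
maximizes the Breslow partial likelihood on a grid.
"""

from __future__ import annotations

import math

import numpy as np

LABELS = {
    3: ("low", "intermediate", "high"),
    4: ("low", "intermediate-low", "intermediate-high", "high"),
}


def rounding_rule_label(mean_score: float, version: str, granularity: int) -> str:
    """Stratum from the decimal-handling prose: nearest-integer rounding
    (original), ceiling (modified), or their fusion switching at 2 (3-S) /
    3 (4-S) (hybrid). Works in integer tenths to dodge float edges."""
    m10 = round(mean_score * 10)
    nearest = (m10 + 5) // 10
    ceiling = -(-m10 // 10)
    if version == "original":
        k = nearest
    elif version == "modified":
        k = ceiling
    elif version == "hybrid":
        switch = 2 if granularity == 3 else 3
        k = nearest if m10 < switch * 10 else ceiling
    else:
        raise ValueError(version)
    k = min(max(k, 1), granularity)
    return LABELS[granularity][k - 1]


def cindex_bruteforce(times, observed, pred) -> float:
    """Harrell's C by explicit pair enumeration.

    Usable pairs: distinct times where the earlier subject has an event,
    or equal times with exactly one event (the event subject fails first),
    or equal times with two events (half credit). Tied predictors on a
    usable pair give half credit.
    """
    t = np.asarray(times, float)
    e = np.asarray(observed, bool)
    x = np.asarray(pred, float)
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                if e[i] and e[j]:
                    den += 1
                    num += 0.5
                elif e[i] != e[j]:
                    first, second = (i, j) if e[i] else (j, i)
                    den += 1
                    if x[first] > x[second]:
                        num += 1
                    elif x[first] == x[second]:
                        num += 0.5
                continue
            first, second = (i, j) if t[i] < t[j] else (j, i)
            if not e[first]:
                continue
            den += 1
            if x[first] > x[second]:
                num += 1
            elif x[first] == x[second]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError("no usable pairs")
    return num / den


def km_empirical(times) -> callable:
    """Empirical survival function (no censoring)."""
    t = np.sort(np.asarray(times, float))

    def S(x: float) -> float:
        return float(np.mean(t > x))

    return S


def breslow_loglik(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for a single covariate."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    xv = np.asarray(x, float)
    ll = 0.0
    for et in np.unique(t[e]):
        fail = (t == et) & e
        risk = t >= et
        d = fail.sum()
        ll += beta * xv[fail].sum() - d * math.log(np.exp(beta * xv[risk]).sum())
    return ll


def cox_grid_hr(times, events, x, lo=-4.0, hi=4.0, steps=8001) -> float:
    """Hazard ratio from a grid search over the Breslow partial likelihood."""
    grid = np.linspace(lo, hi, steps)
    lls = [breslow_loglik(b, times, events, x) for b in grid]
    return float(np.exp(grid[int(np.argmax(lls))]))


def logistic_newton(X: np.ndarray, y: np.ndarray, iters: int = 50) -> np.ndarray:
    """Logistic MLE by plain Newton iteration (intercept included in X)."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None])
        g = X.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta
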