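"""Independent brute-force oracles used by the unit and acceptance suites.

Each is deliberately naive (enumeration, O(n^2) pair counting, exhaustive
permutation) and shares no code with the implementation it checks.
"""

from itertools import combinations
from math import lgamma

import numpy as np


def hwe_oracle(a: int, b: int, c: int) -> float:
    """Exact conditional HWE p by full enumeration over het counts."""
    n = a + b + c
    r = 2 * min(a, c) + b
    probs = {}
    for h in range(r % 2, min(r, 2 * n - r) + 1, 2):
        na = (r - h) // 2
        nc = n - na - h
        lp = (
            lgamma(n + 1) - lgamma(na + 1) - lgamma(h + 1) - lgamma(nc + 1)
            + h * np.log(2)
            + lgamma(r + 1) + lgamma(2 * n - r + 1) - lgamma(2 * n + 1)
        )
        probs[h] = np.exp(lp)
    tot = sum(probs.values())
    pobs = probs[b] / tot
    return sum(p for p in probs.values() if p / tot <= pobs * (1 + 1e-10)) / tot


def auc_pair_counting(scores, labels) -> float:
    """O(n^2) enumeration of case/control pairs, ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    cases = s[y == 1]
    controls = s[y == 0]
    total = 0.0
    for a in cases:
        for b in controls:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(cases) * len(controls))


def mwu_exact_permutation_p(xa, xb) -> float:
    """Two-sided exact permutation p-value of the Mann-Whitney U statistic."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    pooled = np.concatenate([xa, xb])
    n, na = pooled.size, xa.size

    def u_of(idx):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        u = 0.0
        for a in grp:
            for b in rest:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_of(range(na))
    mu = na * (n - na) / 2
    dev_obs = abs(u_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(u_of(idx) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def newton_logistic_oracle(X, y, tol=1e-12, max_iter=200):
    """Plain Newton-Raphson maximum-likelihood logistic fit (with intercept)."""
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        grad = X.T @ (y - mu)
        H = (X * (mu * (1 - mu))[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def chi2_2xk_oracle(table):
    """Pearson chi-squared from the definition (no correction)."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows @ cols / t.sum()
    stat = ((t - expected) ** 2 / expected).sum()
    from scipy.stats import chi2

    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, chi2.sf(stat, dof)


def spearman_oracle(x, y):
    """Pearson correlation of hand-computed average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(v.size)
        order = np.argsort(v, kind="mergesort")
        sv = v[order]
        i = 0
        while i < v.size:
            j = i
            while j < v.size and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
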