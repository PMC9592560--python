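"""Independent brute-force oracles used by the test suite.

Deliberately naive, loop-based transcriptions of the published formulas —
kept free of any code path from the package so they can serve as an
independent cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, poisson, rankdata
from scipy.stats import hypergeom


def gsva_oracle(X, set_idx, kernel="gaussian", tau=1.0, statistic="diff-of-extremes"):
    """Naive kernel-CDF + weighted KS random-walk enrichment, one loop at a time."""
    p, n = X.shape
    Z = np.zeros((p, n))
    for i in range(p):
        if kernel == "gaussian":
            h = np.std(X[i], ddof=1) / 4.0
            h = h if h > 0 else 1e-8
            for j in range(n):
                Z[i, j] = np.mean([norm.cdf((X[i, j] - X[i, k]) / h) for k in range(n)])
        elif kernel == "poisson":
            for j in range(n):
                Z[i, j] = np.mean([poisson.cdf(X[i, j], X[i, k] + 0.5) for k in range(n)])
        elif kernel == "none":
            for j in range(n):
                Z[i, j] = sum(X[i, k] <= X[i, j] for k in range(n)) / n
        else:
            raise ValueError(kernel)
    set_idx = set(set_idx)
    m = len(set_idx)
    out = []
    for j in range(n):
        # decreasing CDF, ties by input gene order
        order = sorted(range(p), key=lambda i: (-Z[i, j], i))
        rank = {g: r + 1 for r, g in enumerate(order)}
        stat = {i: abs(p / 2.0 - rank[i]) ** tau for i in range(p)}
        wsum = sum(stat[i] for i in set_idx)
        walk, v = [], 0.0
        for i in order:
            if i in set_idx:
                v += stat[i] / wsum
            else:
                v -= 1.0 / (p - m)
            walk.append(v)
        vmax = max(max(walk), 0.0)
        vmin = min(min(walk), 0.0)
        if statistic == "diff-of-extremes":
            out.append(vmax + vmin)
        else:
            out.append(vmax if vmax > -vmin else vmin)
    return np.array(out)


def tmm_oracle(counts, logratio_trim=0.3, sum_trim=0.05):
    """Literal transcription of the trimmed-mean-of-M-values formulas."""
    X = np.asarray(counts, dtype=float)
    lib = X.sum(axis=0)
    # reference: upper-quartile depth closest to the mean upper-quartile depth
    f75 = np.array([np.quantile(X[:, j], 0.75) / lib[j] for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(X.shape[1]):
        obs, refc = X[:, j], X[:, ref]
        keep = (obs > 0) & (refc > 0)
        o, r = obs[keep] / lib[j], refc[keep] / lib[ref]
        M = np.log2(o / r)
        A = 0.5 * np.log2(o * r)
        w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (lib[ref] - refc[keep]) / (
            lib[ref] * refc[keep]
        )
        if np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = M.size
        loM, hiM = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        loA, hiA = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rM, rA = rankdata(M), rankdata(A)
        sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        f = np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel])
        factors.append(2.0**f)
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def fisher_two_sided_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all 2x2 tables with the observed margins whose
    probability does not exceed the observed table's (with a small relative
    tolerance for float ties, as is conventional).
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def one_way_anova_oracle(groups):
    """Hand variance-components computation for the one-way random model."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    a = len(groups)
    sizes = np.array([len(g) for g in groups])
    N = sizes.sum()
    allv = np.concatenate(groups)
    grand = allv.mean()
    msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (a - 1)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - a)
    k0 = (N - (sizes**2).sum() / N) / (a - 1)
    s2b = max((msb - msw) / k0, 0.0)
    icc = s2b / (s2b + msw) if s2b + msw > 0 else 0.0
    return {"msb": msb, "msw": msw, "k0": k0, "s2b": s2b, "s2w": msw, "icc": icc, "grand": grand}
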