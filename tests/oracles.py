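"""Independent brute-force oracles used to validate the statistical paths.

Everything here is deliberately naive (log-factorial enumeration, full
permutation/sign enumeration, direct step-up) and shares no code with the
implementation under test.
"""

from __future__ import annotations

from itertools import combinations, product
from math import exp, lgamma

import numpy as np
from scipy.stats import rankdata


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_oracle(a: int, b: int, c: int, d: int,
                  alternative: str = "two-sided") -> float:
    """Fisher exact p by hypergeometric tail enumeration over one margin."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    logden = _log_comb(n, c1)
    probs = {
        k: exp(_log_comb(r1, k) + _log_comb(r2, c1 - k) - logden)
        for k in range(kmin, kmax + 1)
    }
    pa = probs[a]
    if alternative == "two-sided":
        return min(1.0, sum(p for p in probs.values() if p <= pa * (1 + 1e-12)))
    if alternative == "greater":
        return min(1.0, sum(p for k, p in probs.items() if k >= a))
    if alternative == "less":
        return min(1.0, sum(p for k, p in probs.items() if k <= a))
    raise ValueError(alternative)


def mannwhitney_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of labelings.

    Returns (U of the first sample, p).  Assumes no ties across the pooled
    data (the exact regime).
    """
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_stat(xs, ys):
        return sum(xi > yj for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    nm = nx * len(y)
    lo, hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    total = extreme = 0
    idx = list(range(len(pooled)))
    for chosen in combinations(idx, nx):
        cs = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in cs]
        u = u_stat(xs, ys)
        total += 1
        if u <= lo or u >= hi:
            extreme += 1
    return float(u_obs), extreme / total


def wilcoxon_oracle(diffs) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Zeros are dropped first; assumes no ties among |d|.
    Returns (W+ statistic, p).
    """
    d = [x for x in diffs if x != 0]
    ranks = rankdata([abs(x) for x in d])
    w_obs = float(sum(r for r, x in zip(ranks, d) if x > 0))
    total_rank = float(ranks.sum())
    lo, hi = min(w_obs, total_rank - w_obs), max(w_obs, total_rank - w_obs)
    count = extreme = 0
    for signs in product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count += 1
        if w <= lo or w >= hi:
            extreme += 1
    return w_obs, extreme / count


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up, written directly from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


def beta_loglik(params, y, x):
    """Beta-regression log-likelihood (logit mean link, constant phi)."""
    from scipy.special import betaln

    beta = np.asarray(params[:-1])
    phi = exp(params[-1])
    mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(np.sum((a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
                        - betaln(a, b)))


def beta_brute_force(y, x, spans=3.0, steps=13, rounds=7):
    """Maximize the beta log-likelihood by iterated grid refinement.

    Independent of any model-fitting library: a coarse grid around the
    logit-OLS start is repeatedly zoomed.  Returns the (beta..., log phi)
    vector at the maximum.
    """
    logit_y = np.log(y / (1 - y))
    b0, *_ = np.linalg.lstsq(x, logit_y, rcond=None)
    center = np.append(b0, np.log(10.0))
    width = np.full(len(center), spans)
    best = center.copy()
    best_ll = beta_loglik(best, y, x)
    for _ in range(rounds):
        grids = [np.linspace(c - w, c + w, steps)
                 for c, w in zip(center, width)]
        for point in product(*grids):
            ll = beta_loglik(np.array(point), y, x)
            if ll > best_ll:
                best_ll, best = ll, np.array(point)
        center = best.copy()
        width = width / (steps - 1) * 2.5
    return best, best_ll


def binom_interval(n: int, p: float, level: float = 0.99) -> tuple[float, float]:
    """Exact binomial central interval for an observed proportion."""
    from scipy.stats import binom

    alpha = (1 - level) / 2
    return binom.ppf(alpha, n, p) / n, binom.ppf(1 - alpha, n, p) / n
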