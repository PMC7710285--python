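"""Independent brute-force reference implementations used only by tests.

Each function here is written directly from the defining formula or by
exhaustive enumeration, deliberately sharing no code with the package, so
that agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(p):
    """BH adjusted p-values by the literal step-up definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for i_rank, idx in enumerate(order, start=1):
        candidates = []
        for j_rank, jdx in enumerate(order, start=1):
            if p[jdx] >= p[idx]:
                candidates.append(min(1.0, m * p[jdx] / j_rank))
        q[idx] = min(candidates)
    return np.array(q)


def ks_statistic(x, y):
    """sup |ECDF_x - ECDF_y| by sweeping every pooled breakpoint."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def wilcoxon_exact(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Assumes no ties.  Returns (rank_sum_of_x, p) with the two-sided p
    computed as 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n = len(x), len(x) + len(y)
    w_obs = sum(rank_of[v] for v in x)
    u_obs = w_obs - n1 * (n1 + 1) / 2

    us = []
    for combo in itertools.combinations(range(n), n1):
        w = sum(i + 1 for i in combo)
        us.append(w - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


def clopper_pearson_bisect(successes, total, level=0.95, tol=1e-10):
    """Exact CI bounds by bisection on binomial tail sums."""

    def binom_pmf(k, n, p):
        return math.comb(n, k) * p ** k * (1 - p) ** (n - k)

    def upper_tail(p):  # P(X >= successes)
        return sum(binom_pmf(k, total, p) for k in range(successes, total + 1))

    def lower_tail(p):  # P(X <= successes)
        return sum(binom_pmf(k, total, p) for k in range(0, successes + 1))

    alpha = 1 - level

    if successes == 0:
        lower = 0.0
    else:
        # upper_tail increases in p; find p with upper_tail(p) = alpha/2
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if upper_tail(mid) > alpha / 2:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        lower = (lo + hi) / 2
    if successes == total:
        upper = 1.0
    else:
        # lower_tail decreases in p; find p with lower_tail(p) = alpha/2
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if lower_tail(mid) > alpha / 2:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        upper = (lo + hi) / 2
    return lower, upper


def ssgsea_score(expr, in_set, alpha=0.25):
    """ssGSEA enrichment score for one sample by the literal running sum.

    ``expr`` is a vector of expression values, ``in_set`` a boolean mask.
    Ties broken by original index, matching a stable descending sort.
    """
    n = len(expr)
    order = sorted(range(n), key=lambda i: (-expr[i], i))
    ranks = {}
    for pos, idx in enumerate(order):
        ranks[idx] = n - pos  # top of the list gets rank n
    sum_w = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = sum(1 for i in range(n) if not in_set[i])
    running_in = running_out = 0.0
    es = 0.0
    for idx in order:
        if in_set[idx]:
            running_in += ranks[idx] ** alpha / sum_w
        else:
            running_out += 1.0 / n_out
        es += running_in - running_out
    return es


def public_clonotypes(samples, min_samples=2):
    """Brute-force set scan for clonotypes present in >= min_samples samples."""
    all_keys = set()
    for s in samples:
        all_keys |= set(s.clonotypes)
    return sorted(k for k in all_keys
                  if sum(1 for s in samples if k in s.clonotypes) >= min_samples)


def shannon_entropy_direct(counts, base=2):
    total = sum(counts)
    h = 0.0
    for c in counts:
        p = c / total
        h -= p * math.log(p, base)
    return h


def morisita_horn_direct(xd, yd):
    keys = set(xd) | set(yd)
    xs = {k: xd.get(k, 0) for k in keys}
    ys = {k: yd.get(k, 0) for k in keys}
    X = sum(xs.values())
    Y = sum(ys.values())
    num = 2 * sum(xs[k] * ys[k] for k in keys)
    den = (sum(v * v for v in xs.values()) / X ** 2
           + sum(v * v for v in ys.values()) / Y ** 2) * X * Y
    return num / den
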