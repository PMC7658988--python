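"""Independent brute-force oracles used to check the statistical routines.

Everything here is enumeration or direct formula application, kept
deliberately separate from the package's code paths.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2, rankdata


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, with U the
    Mann-Whitney statistic of the first group. Assumes no ties.
    """
    x, y = list(x), list(y)
    pooled = x + y
    ranks = rankdata(pooled)
    nx, ny = len(x), len(y)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in combinations(range(nx + ny), nx):
        r = ranks[list(idx)].sum()
        us.append(r - nx * (nx + 1) / 2)
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def bh_stepup(pvals) -> np.ndarray:
    """Textbook BH step-up: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_enumeration(k, K, n, N) -> float:
    """P(|draw ∩ marked| >= k) by enumerating all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def fisher_enumeration(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric masses <= observed mass."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def mass(aa):
        return comb(r1, aa) * comb(r2, c1 - aa) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = mass(a)
    return sum(m for aa in range(lo, hi + 1) if (m := mass(aa)) <= obs * (1 + 1e-9))


def chisq_gof(observed, fractions) -> float:
    """Direct Pearson goodness-of-fit formula, df = S - 1."""
    obs = np.asarray(observed, dtype=float)
    expected = obs.sum() * np.asarray(fractions, dtype=float)
    stat = np.sum((obs - expected) ** 2 / expected)
    return float(chi2.sf(stat, obs.size - 1))


def ari_contingency(a, b) -> float:
    """ARI from the contingency-table formula."""
    a, b = list(a), list(b)
    ua, ub = sorted(set(a)), sorted(set(b))
    nij = np.zeros((len(ua), len(ub)), dtype=int)
    for x, y in zip(a, b):
        nij[ua.index(x), ub.index(y)] += 1
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in nij.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in nij.sum(axis=0))
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
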