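"""Independent brute-force oracles used to validate the statistical kernels.

Every function here recomputes its quantity from first principles
(exhaustive enumeration, literal running sums, closed-form counting) and
deliberately shares no code with the package implementations.
"""

from itertools import combinations, product
from math import comb

import numpy as np


def hypergeom_pmf(a, row1, row2, col1):
    """P(top-left cell = a) for fixed margins (row1, row2, col1)."""
    n = row1 + row2
    return comb(row1, a) * comb(row2, col1 - a) / comb(n, col1)


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by enumerating all tables with fixed margins."""
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom_pmf(x, row1, row2, col1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def bh_step_up(pvalues):
    """Literal Benjamini-Hochberg: sort, scale by m/rank, cummin from the top."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def average_ranks(values):
    """Average (midrank) ranks computed by explicit counting."""
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def spearman(x, y):
    """Spearman rho: Pearson correlation of midranks, computed longhand."""
    rx, ry = average_ranks(x), average_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx)
    dy = sum((b - my) ** 2 for b in ry)
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy) ** 0.5


def signed_rank_two_sided(diffs):
    """Exact signed-rank p by enumerating every sign pattern (Pratt zeros)."""
    diffs = list(diffs)
    ranks = average_ranks([abs(d) for d in diffs])
    nz = [(r, d) for r, d in zip(ranks, diffs) if d != 0]
    if not nz:
        return 1.0
    rs = [r for r, _ in nz]
    w_obs = sum(r for r, d in nz if d > 0)
    m = len(rs)
    ws = []
    for signs in product([0, 1], repeat=m):
        ws.append(sum(r for r, s in zip(rs, signs) if s))
    n_total = len(ws)
    p_le = sum(1 for w in ws if w <= w_obs + 1e-12) / n_total
    p_ge = sum(1 for w in ws if w >= w_obs - 1e-12) / n_total
    return min(1.0, 2 * min(p_le, p_ge))


def rank_sum_two_sided(a, b):
    """Exact rank-sum p by enumerating every group assignment."""
    pooled = list(a) + list(b)
    ranks = average_ranks(pooled)
    n, n1 = len(pooled), len(a)
    center = n1 * (n + 1) / 2.0
    obs = abs(sum(ranks[:n1]) - center)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


def ssgsea_running_sum(genes, values, gene_set, alpha):
    """Literal ssGSEA: walk genes by descending expression, accumulate the
    weighted in-set ECDF minus the unweighted out-set ECDF."""
    ranks = dict(zip(genes, average_ranks(values)))
    order = sorted(genes, key=lambda g: (-ranks[g], g))
    total_in = sum(ranks[g] ** alpha for g in order if g in gene_set)
    n_out = sum(1 for g in order if g not in gene_set)
    if total_in == 0 or n_out == 0:
        return 0.0
    p_in = p_out = 0.0
    score = 0.0
    for g in order:
        if g in gene_set:
            p_in += ranks[g] ** alpha / total_in
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def hypergeom_upper_tail(overlap, universe, set_size, draw):
    """P(X >= overlap) by summing counted configurations."""
    total = comb(universe, draw)
    hits = 0
    for k in range(overlap, min(set_size, draw) + 1):
        hits += comb(set_size, k) * comb(universe - set_size, draw - k)
    return hits / total
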