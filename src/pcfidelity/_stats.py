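"""Shared statistical primitives.

Small-sample exact paths are kept here so that every module applies the
same conventions: two-sided Fisher tests, Benjamini-Hochberg step-up
adjustment, average-rank Spearman correlation, exact Wilcoxon rank-sum
for small pooled n, and a Pratt-convention signed-rank test with an
exact dynamic-programming null for n <= 25.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# pooled-n threshold below which the rank-sum null is enumerated exactly
_EXACT_RANKSUM_N = 16
# number of non-zero differences up to which the signed-rank null is exact
_EXACT_SIGNRANK_N = 25


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same input order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def hypergeom_sf_p(overlap: int, universe: int, set_size: int, draw: int) -> float:
    """One-sided over-representation p: P(X >= overlap), X ~ Hypergeom."""
    if universe <= 0:
        raise ValueError("universe must be non-empty")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, draw))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All pairwise Spearman rhos between columns of `a` and columns of `b`.

    Both matrices share the row (feature) axis. Columns that are constant
    yield NaN rows/columns, matching :func:`spearman_rho`.
    """
    ra = np.apply_along_axis(stats.rankdata, 0, a)
    rb = np.apply_along_axis(stats.rankdata, 0, b)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    na = np.sqrt((ra * ra).sum(axis=0))
    nb = np.sqrt((rb * rb).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ra.T @ rb) / np.outer(na, nb)
    out[na == 0, :] = np.nan
    out[:, nb == 0] = np.nan
    return out


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration of group assignments when the pooled size is
    small (handles ties through midranks); otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    n1, n2 = a.size, b.size
    if n1 + n2 <= _EXACT_RANKSUM_N:
        return _rank_sum_exact(pooled, n1)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _rank_sum_exact(pooled: np.ndarray, n1: int) -> float:
    ranks = stats.rankdata(pooled)
    n = pooled.size
    center = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - center)
    hits = 0
    total = comb(n, n1)
    for idx in combinations(range(n), n1):
        if abs(ranks[list(idx)].sum() - center) >= obs - 1e-12:
            hits += 1
    return hits / total


def signed_rank_test(x, y=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value, Pratt zero handling.

    Zero differences are ranked together with the non-zero ones and then
    discarded. The null distribution of W+ is computed exactly (dynamic
    programming over the 2^m sign assignments) for up to 25 non-zero
    differences, and by normal approximation with continuity and tie
    corrections above that.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two paired observations")
    ranks = stats.rankdata(np.abs(d))  # zeros included in the ranking
    nz = d != 0
    m = int(nz.sum())
    if m == 0:
        return 1.0
    r = ranks[nz]
    w_plus = float(r[d[nz] > 0].sum())
    if m <= _EXACT_SIGNRANK_N:
        return _signed_rank_exact(r, w_plus)
    return _signed_rank_normal(ranks, nz, w_plus)


def _signed_rank_exact(r: np.ndarray, w_plus: float) -> float:
    # doubled ranks are integers even with midrank ties
    r2 = np.rint(2 * r).astype(int)
    dist = np.zeros(r2.sum() + 1)
    dist[0] = 1.0
    for ri in r2:
        shifted = np.zeros_like(dist)
        shifted[ri:] = dist[: dist.size - ri]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def _signed_rank_normal(ranks: np.ndarray, nz: np.ndarray, w_plus: float) -> float:
    n = ranks.size
    n0 = n - int(nz.sum())
    mean = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
    # tie correction over non-zero |d| groups
    _, counts = np.unique(ranks[nz], return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))
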