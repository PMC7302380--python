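"""Independent reference implementations used only by the tests.

These deliberately avoid the package's code paths: ranks are computed
by explicit tie-grouping, Spearman p-values from the t formula via
scipy.special, BH by the sorted-p textbook formula, and the null
expectation of cross-lineage edges by literal enumeration of edge
subsets (small graphs) or hypergeometric pair-inclusion counting.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from scipy import special


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks with explicit tie grouping (1-based)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho as Pearson on average ranks; two-sided p from the
    large-sample t approximation. Returns (nan, nan) for a constant
    vector."""
    rx, ry = average_ranks(x), average_ranks(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    rho = float((sx * sy).sum() / denom)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(special.stdtr(n - 2, -abs(t)))
    return rho, p


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg by the sorted-p formula q_(k) = min_{j>=k} p_(j) n/j."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def brute_force_edges(rel: np.ndarray, otu_ids, rho_min: float, q_max: float):
    """Edge set of the co-occurrence network, recomputed from scratch.

    Constant columns are excluded from the test family, matching the
    documented handling of undefined rank correlations.
    """
    n, p = rel.shape
    pairs, rhos, ps = [], [], []
    for i, j in itertools.combinations(range(p), 2):
        rho, pv = spearman_rho_p(rel[:, i], rel[:, j])
        if math.isnan(rho):
            continue
        pairs.append((i, j))
        rhos.append(rho)
        ps.append(pv)
    qs = bh_adjust(np.array(ps)) if ps else np.array([])
    edges = set()
    for (i, j), rho, q in zip(pairs, rhos, qs):
        if rho > rho_min and rho > 0 and q < q_max:
            edges.add(frozenset((otu_ids[i], otu_ids[j])))
    return edges


@lru_cache(maxsize=None)
def exhaustive_expected_cross(M: int, m: int, K: int) -> float:
    """Mean cross-edge count over ALL graphs with m of M possible pairs,
    K of which are cross-lineage.

    For small M every m-subset is enumerated literally; for larger M the
    count is obtained by pair-inclusion counting: each of the K cross
    pairs is contained in C(M-1, m-1) of the C(M, m) subsets.
    """
    if m == 0:
        return 0.0
    if M <= 16:
        total = 0
        count = 0
        for subset in itertools.combinations(range(M), m):
            total += sum(1 for e in subset if e < K)
            count += 1
        return total / count
    return K * math.comb(M - 1, m - 1) / math.comb(M, m)
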