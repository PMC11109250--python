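"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, double loops, closed
forms) and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Uses the standard doubled-tail convention ``min(1, 2 * min(P(W <= w),
    P(W >= w)))`` over every way of choosing which pooled observations form
    the first group (mid-ranks for ties).
    """
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    lo = hi = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        lo += w <= w_obs + 1e-12
        hi += w >= w_obs - 1e-12
        total += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def welch_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite df from the textbook formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared of independence, summed term by term."""
    table = np.asarray(table, float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2, (table.shape[0] - 1) * (table.shape[1] - 1)


def rand_index_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """Unadjusted Rand index by O(n^2) explicit pair counting."""
    n = len(x)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_x = x[i] == x[j]
            same_y = y[i] == y[j]
            agree += same_x == same_y
    return agree / (n * (n - 1) / 2)


def knn_bruteforce(coords: np.ndarray, k: int) -> np.ndarray:
    """Exact k nearest neighbors by full pairwise distances, index tie-break."""
    n = coords.shape[0]
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        d = [(float(np.sum((coords[i] - coords[j]) ** 2)), j) for j in range(n) if j != i]
        d.sort()
        out[i] = [j for _, j in d[:k]]
    return out


def similarity_recount(
    neighbors: np.ndarray,
    species: np.ndarray,
    labels: np.ndarray,
    type_a: str,
    type_b: str,
    tag_a: str,
    tag_b: str,
) -> float:
    """Double-loop recount of the mean cross-species neighbor score."""
    n_a = n_b = 0
    total = 0
    for i in range(len(labels)):
        if species[i] == tag_a and labels[i] == type_a:
            n_a += 1
            for j in neighbors[i]:
                if species[j] == tag_b and labels[j] == type_b:
                    total += 1
        elif species[i] == tag_b and labels[i] == type_b:
            n_b += 1
            for j in neighbors[i]:
                if species[j] == tag_a and labels[j] == type_a:
                    total += 1
    return total / (n_a + n_b)


def spearman_d2(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho via 1 - 6*sum(d^2)/(n(n^2-1)); valid without ties."""
    ra = np.argsort(np.argsort(a)) + 1
    rb = np.argsort(np.argsort(b)) + 1
    n = len(a)
    return 1.0 - 6.0 * float(((ra - rb) ** 2).sum()) / (n * (n**2 - 1))
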