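"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: binomial tails
by term-by-term summation, average-linkage clustering by O(n^3) recompute,
collinear chains by exhaustive DFS enumeration, and the Tukey statistic by
direct loops over the defining sums.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def binom_upper_tail_sum(k: int, n: int, e: float) -> float:
    """P(X >= k), summed term by term with exact binomial coefficients."""
    return sum(
        math.comb(n, x) * (e**x) * ((1.0 - e) ** (n - x)) for x in range(k, n + 1)
    )


def average_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge-height sequence of average-linkage clustering, recomputed from
    the full pairwise distance matrix at every step (O(n^3))."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            key = (d, min(clusters[a] + clusters[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        heights.append(d)
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return heights


def enumerate_best_chain(
    anchors, gap_penalty, max_gap_genes, min_anchors
) -> tuple[float, tuple]:
    """Best chain score over ALL monotone anchor subsets (both orientations),
    by depth-first enumeration.  Anchors are (query_index, target_index,
    score) triples; returns (best_score, anchor index tuple) or (-inf, ())."""
    order = sorted(range(len(anchors)), key=lambda i: anchors[i][0])
    best_score, best_path = float("-inf"), ()

    def extend(path, score, sign):
        nonlocal best_score, best_path
        if len(path) >= min_anchors and score > best_score + 1e-12:
            best_score, best_path = score, tuple(path)
        last = path[-1]
        lq, lt, _ = anchors[last]
        for i in order:
            q, t, s = anchors[i]
            dq = q - lq
            dt = sign * (t - lt)
            if 1 <= dq <= max_gap_genes and 1 <= dt <= max_gap_genes:
                path.append(i)
                extend(path, score + s - gap_penalty * ((dq - 1) + (dt - 1)), sign)
                path.pop()

    for sign in (1, -1):
        for i in order:
            extend([i], anchors[i][2], sign)
    return best_score, best_path


def tukey_oracle(y: np.ndarray) -> tuple[float, float]:
    """(F, p) for the one-df non-additivity test, computed with plain loops."""
    from scipy.stats import f as fdist

    r, c = y.shape
    grand = y.mean()
    rowm = [y[i].mean() for i in range(r)]
    colm = [y[:, j].mean() for j in range(c)]
    n_stat = sum(
        y[i, j] * (rowm[i] - grand) * (colm[j] - grand)
        for i in range(r) for j in range(c)
    )
    ss_rows = sum((m - grand) ** 2 for m in rowm)
    ss_cols = sum((m - grand) ** 2 for m in colm)
    ss_nonadd = n_stat**2 / (ss_rows * ss_cols)
    ss_resid = sum(
        (y[i, j] - rowm[i] - colm[j] + grand) ** 2
        for i in range(r) for j in range(c)
    )
    dfree = (r - 1) * (c - 1) - 1
    f_stat = ss_nonadd / ((ss_resid - ss_nonadd) / dfree)
    return f_stat, float(fdist.sf(f_stat, 1, dfree))
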