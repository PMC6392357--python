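"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive scans, recursive
enumeration) and shares no code with the package implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- average-linkage clustering ---------------------------------------


def average_linkage_partition(ids, dmat, threshold):
    """Exhaustive agglomerative average linkage cut at a threshold.

    Repeatedly merges the cluster pair with the smallest mean pairwise
    distance while that minimum is <= threshold.
    """
    clusters = [frozenset([i]) for i in range(len(ids))]
    while len(clusters) > 1:
        best_d, best_pair = None, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ds = [dmat[i][j] for i in clusters[a] for j in clusters[b]]
            d = sum(ds) / len(ds)
            if best_d is None or d < best_d - 1e-15:
                best_d, best_pair = d, (a, b)
        if best_d > threshold:
            break
        a, b = best_pair
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return {frozenset(ids[i] for i in c) for c in clusters}


# -- integer matrices with fixed marginals ----------------------------


def matrices_with_marginals(row_totals, col_totals):
    """Yield every non-negative integer matrix with the given marginals."""
    rows, cols = list(row_totals), list(col_totals)

    def compositions(total, bounds):
        if len(bounds) == 1:
            if total <= bounds[0]:
                yield (total,)
            return
        for first in range(min(total, bounds[0]) + 1):
            for rest in compositions(total - first, bounds[1:]):
                yield (first,) + rest

    def rec(i, remaining_cols, acc):
        if i == len(rows):
            if all(r == 0 for r in remaining_cols):
                yield np.array(acc)
            return
        for row in compositions(rows[i], remaining_cols):
            yield from rec(i + 1,
                           [r - x for r, x in zip(remaining_cols, row)],
                           acc + [row])

    yield from rec(0, cols, [])


def entropy_of(matrix):
    p = np.asarray(matrix, dtype=float).ravel()
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum())


def h2_prime_exhaustive(matrix):
    """H2' with true integer entropy extremes by full enumeration."""
    a = np.asarray(matrix)
    h2 = entropy_of(a)
    entropies = [entropy_of(m) for m in
                 matrices_with_marginals(a.sum(axis=1), a.sum(axis=0))]
    h2max, h2min = max(entropies), min(entropies)
    if h2max - h2min < 1e-12:
        return 1.0
    return (h2max - h2) / (h2max - h2min)


# -- Barber modularity by exhaustive partition search -----------------


def set_partitions(items):
    """All set partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def barber_q_oracle(matrix, row_groups, col_groups):
    a = np.asarray(matrix, dtype=float)
    F = a.sum()
    k, d = a.sum(axis=1), a.sum(axis=0)
    q = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if row_groups[i] == col_groups[j]:
                q += a[i, j] - k[i] * d[j] / F
    return q / F


def max_barber_q_exhaustive(matrix):
    """Maximum Barber modularity over all partitions of all nodes."""
    a = np.asarray(matrix, dtype=float)
    R, C = a.shape
    nodes = [("r", i) for i in range(R)] + [("c", j) for j in range(C)]
    best = -np.inf
    for part in set_partitions(nodes):
        rg, cg = [0] * R, [0] * C
        for g, block in enumerate(part):
            for side, idx in block:
                if side == "r":
                    rg[idx] = g
                else:
                    cg[idx] = g
        best = max(best, barber_q_oracle(a, rg, cg))
    return best


# -- NODF by direct formula -------------------------------------------


def nodf_direct(matrix, weighted=False):
    """Paired-overlap / decreasing-fill NODF, written independently."""
    a = np.asarray(matrix, dtype=float)

    def sort_axis(m):
        key = m.sum(axis=1) if weighted else (m > 0).sum(axis=1)
        order = sorted(range(m.shape[0]), key=lambda i: (-key[i], i))
        return m[order]

    def pair_scores(m):
        out = []
        for i, j in itertools.combinations(range(m.shape[0]), 2):
            u, l = m[i], m[j]
            nz_l = (l > 0).sum()
            if nz_l == 0:
                out.append(0.0)
                continue
            if weighted:
                if l.sum() >= u.sum():
                    out.append(0.0)
                    continue
                out.append(100.0 * ((l > 0) & (l < u)).sum() / nz_l)
            else:
                if nz_l >= (u > 0).sum():
                    out.append(0.0)
                    continue
                out.append(100.0 * ((l > 0) & (u > 0)).sum() / nz_l)
        return out

    scores = pair_scores(sort_axis(a)) + pair_scores(sort_axis(a.T))
    return float(np.mean(scores))
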