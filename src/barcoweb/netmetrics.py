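"""Bipartite network metrics: H2' specialization, interaction evenness,
generality/vulnerability, NODF/WNODF nestedness and Barber modularity.

All metrics operate on a non-negative insect x plant count matrix.  H2'
standardizes the two-dimensional Shannon entropy of the interaction
proportions between its feasible extremes under fixed integer marginal
totals (greedy heuristics for the extremes, matching the usual integer
convention).  NODF averages paired overlap under decreasing fill over all
row and column pairs after canonical sorting by marginal totals.  Barber
bipartite modularity Q = (1/F) * sum_ij (A_ij - k_i d_j / F) delta(g_i, g_j)
is maximized with a weighted label-propagation algorithm plus an
agglomerative refinement stage (LPAwb+-style), restarted from several
random orders.

Webs smaller than 2 x 2 (or empty) yield NaN throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


def _as_array(web) -> np.ndarray:
    if hasattr(web, "matrix"):
        web = web.matrix
    if isinstance(web, pd.DataFrame):
        web = web.to_numpy()
    a = np.asarray(web, dtype=float)
    if a.ndim != 2:
        raise ValueError("web must be a 2-D matrix")
    if (a < 0).any():
        raise ValueError("web entries must be non-negative")
    return a


def _degenerate(a: np.ndarray) -> bool:
    return a.shape[0] < 2 or a.shape[1] < 2 or a.sum() == 0


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# -- H2' ---------------------------------------------------------------


def _h2_min_greedy(r: np.ndarray, c: np.ndarray) -> float:
    """Entropy of the most concentrated integer matrix with marginals r, c.

    Classic allocation heuristic: repeatedly pair the largest remaining
    row total with the largest remaining column total (ties by index) and
    allocate the minimum of the two.
    """
    r, c = r.astype(float).copy(), c.astype(float).copy()
    total = r.sum()
    cells = []
    while r.sum() > 1e-9:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        a = min(r[i], c[j])
        cells.append(a)
        r[i] -= a
        c[j] -= a
    return _entropy(np.asarray(cells) / total)


def _h2_max_greedy(r: np.ndarray, c: np.ndarray) -> float:
    """Entropy of a near-uniform (independence-like) integer matrix.

    Start from floor(r_i * c_j / N) and hand out the remaining units one
    at a time to the cell furthest below its continuous target among
    cells whose row and column still have a deficit (row-major ties).
    """
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    total = r.sum()
    target = np.outer(r, c) / total
    a = np.floor(target)
    dr = r - a.sum(axis=1)
    dc = c - a.sum(axis=0)
    while dr.sum() > 1e-9:
        gap = target - a
        mask = (dr[:, None] > 1e-9) & (dc[None, :] > 1e-9)
        gap = np.where(mask, gap, -np.inf)
        i, j = np.unravel_index(int(np.argmax(gap)), gap.shape)
        a[i, j] += 1
        dr[i] -= 1
        dc[j] -= 1
    return _entropy(a.ravel() / total)


def _h2_extremes_exact(r: np.ndarray, c: np.ndarray,
                       cap: int = 50_000) -> tuple[float, float] | None:
    """Exact integer entropy extremes by enumerating all matrices with the
    given marginals; None when the enumeration would be too large.

    An upper bound on the table count (product of per-row composition
    counts) is checked first so pathological marginals skip straight to
    the greedy heuristics without wasted work.
    """
    rows = [int(x) for x in r]
    cols = [int(x) for x in c]
    bound = 1.0
    for t in rows:
        bound *= math.comb(t + len(cols) - 1, len(cols) - 1)
        if bound > cap:
            return None
    total = sum(rows)
    count = 0
    h_max, h_min = -np.inf, np.inf

    def compositions(t, bounds):
        if len(bounds) == 1:
            if t <= bounds[0]:
                yield (t,)
            return
        for first in range(min(t, bounds[0]) + 1):
            for rest in compositions(t - first, bounds[1:]):
                yield (first,) + rest

    def rec(i, remaining, cells):
        nonlocal count, h_max, h_min
        if count > cap:
            return
        if i == len(rows):
            if all(x == 0 for x in remaining):
                count += 1
                h = _entropy(np.array(cells, dtype=float) / total)
                h_max, h_min = max(h_max, h), min(h_min, h)
            return
        for row in compositions(rows[i], remaining):
            rec(i + 1, [x - y for x, y in zip(remaining, row)], cells + list(row))

    rec(0, cols, [])
    if count > cap or not np.isfinite(h_max):
        return None
    return h_max, h_min


def h2_prime(web) -> float:
    """Network-level specialization H2' in [0, 1].

    H2' = (H2max - H2) / (H2max - H2min) with H2 the Shannon entropy of
    the interaction proportions and H2max/H2min its feasible extremes
    under fixed integer marginal totals: exact by enumeration for webs
    below 5x5 (when the enumeration stays small), greedy heuristics
    otherwise.  1 means every consumer is maximally specialized given the
    marginals; 0 means the neutral configuration (counts proportional to
    marginal products).  When the marginals admit only one entropy (e.g.
    a permutation matrix), every feasible web is perfectly specialized
    and 1 is returned.
    """
    a = _as_array(web)
    if _degenerate(a):
        return float("nan")
    total = a.sum()
    h2 = _entropy(a.ravel() / total)
    r, c = a.sum(axis=1), a.sum(axis=0)
    exact = None
    if a.shape[0] < 5 and a.shape[1] < 5 and np.allclose(a, np.round(a)):
        exact = _h2_extremes_exact(np.round(r), np.round(c))
    if exact is not None:
        h2max, h2min = exact
    else:
        h2max = _h2_max_greedy(r, c)
        h2min = _h2_min_greedy(r, c)
    # heuristics bound the true extremes; never let the observed web escape
    h2max = max(h2max, h2)
    h2min = min(h2min, h2)
    if h2max - h2min < 1e-12:
        return 1.0
    return float((h2max - h2) / (h2max - h2min))


# -- evenness and partner diversity ------------------------------------


def interaction_evenness(web, denominator: str = "cells") -> float:
    """Shannon evenness of interactions.

    Entropy of the interaction proportions divided by ln(R*C)
    (``denominator="cells"``) or by ln(number of realized links)
    (``denominator="links"``).
    """
    a = _as_array(web)
    if _degenerate(a):
        return float("nan")
    h = _entropy(a.ravel() / a.sum())
    if denominator == "cells":
        denom = np.log(a.shape[0] * a.shape[1])
    elif denominator == "links":
        denom = np.log((a > 0).sum())
    else:
        raise ValueError(f"unknown denominator: {denominator!r}")
    if denom == 0:
        return float("nan")
    return float(h / denom)


def partner_diversity(web, axis: str = "rows", weighted: bool = True) -> float:
    """Mean (effective) number of partners per node on one side.

    ``axis="rows"`` gives generality (plants per insect), ``axis="columns"``
    vulnerability (insects per plant).  Weighted: sum_i (A_i./A..) *
    exp(H_i) with H_i the node's interaction entropy — the marginal-total
    weighted mean effective partner number.  Qualitative: plain mean
    count of partners on the binary web.
    """
    a = _as_array(web)
    if _degenerate(a):
        return float("nan")
    if axis == "columns":
        a = a.T
    elif axis != "rows":
        raise ValueError(f"unknown axis: {axis!r}")
    totals = a.sum(axis=1)
    keep = totals > 0
    a, totals = a[keep], totals[keep]
    if not weighted:
        return float((a > 0).sum(axis=1).mean())
    weights = totals / totals.sum()
    eff = np.array([np.exp(_entropy(row / t)) for row, t in zip(a, totals)])
    return float((weights * eff).sum())


# -- NODF --------------------------------------------------------------


def _canonical_sort(a: np.ndarray, by: np.ndarray) -> np.ndarray:
    order = np.lexsort((np.arange(len(by)), -by))
    return a[order]


def nodf(web, weighted: bool = False) -> float:
    """NODF nestedness (0-100), binary or weighted (WNODF).

    Rows and columns are first sorted by decreasing marginal totals (ties
    by original index).  A pair (i above j) contributes paired overlap
    only under strictly decreasing fill (binary) or strictly decreasing
    marginal totals (weighted); the weighted overlap counts cells where
    0 < a_jk < a_ik.
    """
    a = _as_array(web)
    if _degenerate(a):
        return float("nan")

    def axis_scores(m: np.ndarray) -> list[float]:
        if weighted:
            m = _canonical_sort(m, m.sum(axis=1))
        else:
            m = _canonical_sort(m, (m > 0).sum(axis=1))
        scores = []
        for i in range(m.shape[0]):
            for j in range(i + 1, m.shape[0]):
                upper, lower = m[i], m[j]
                d_lower = int((lower > 0).sum())
                if d_lower == 0:
                    scores.append(0.0)
                    continue
                if weighted:
                    if lower.sum() >= upper.sum():
                        scores.append(0.0)
                        continue
                    paired = int(((lower > 0) & (lower < upper)).sum())
                else:
                    if d_lower >= int((upper > 0).sum()):
                        scores.append(0.0)
                        continue
                    paired = int(((lower > 0) & (upper > 0)).sum())
                scores.append(100.0 * paired / d_lower)
        return scores

    scores = axis_scores(a) + axis_scores(a.T)
    return float(np.mean(scores)) if scores else float("nan")


# -- Barber modularity via LPAwb+ --------------------------------------


def barber_modularity(web, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber bipartite modularity Q of a given module partition."""
    a = _as_array(web)
    F = a.sum()
    if F == 0:
        return float("nan")
    B = a - np.outer(a.sum(axis=1), a.sum(axis=0)) / F
    match = row_labels[:, None] == col_labels[None, :]
    return float(B[match].sum() / F)


def _lpa_sweep(B: np.ndarray, rlab: np.ndarray, clab: np.ndarray,
               rng: np.random.Generator) -> bool:
    """One label-propagation pass over all nodes; True if anything moved.

    A row node's Q contribution is the sum of B over columns sharing its
    label (and symmetrically for columns), so each node greedily takes the
    opposite side's best-scoring label; a fresh singleton label (score 0)
    is the fallback when every module would lower Q.
    """
    moved = False
    R, C = B.shape
    fresh = int(max(rlab.max(), clab.max())) + 1
    nodes = [("r", i) for i in range(R)] + [("c", j) for j in range(C)]
    rng.shuffle(nodes)
    for side, idx in nodes:
        own = rlab if side == "r" else clab
        other = clab if side == "r" else rlab
        row = B[idx, :] if side == "r" else B[:, idx]
        scores: dict[int, float] = {}
        for lab, b in zip(other, row):
            lab = int(lab)
            scores[lab] = scores.get(lab, 0.0) + b
        best_lab, best = fresh, 0.0
        for lab in sorted(scores):
            if scores[lab] > best + 1e-12:
                best_lab, best = lab, scores[lab]
        current = scores.get(int(own[idx]), 0.0)
        if best_lab != own[idx] and best > current + 1e-12:
            own[idx] = best_lab
            if best_lab == fresh:
                fresh += 1
            moved = True
    return moved


def _agglomerate(a: np.ndarray, B: np.ndarray, rlab: np.ndarray,
                 clab: np.ndarray, rng: np.random.Generator,
                 max_trials: int = 10) -> bool:
    """Try merging module pairs followed by propagation sweeps.

    A merge whose immediate Q gain is zero or negative can still unlock
    better single-node moves afterwards, so candidate pairs are ranked by
    plain-merge gain and the top ones are each tried with sweeps; the
    first trial that improves Q is accepted.
    """
    labels = sorted(set(rlab) | set(clab))
    base = barber_modularity(a, rlab, clab)
    gains = []
    for x in range(len(labels)):
        for y in range(x + 1, len(labels)):
            r2, c2 = rlab.copy(), clab.copy()
            r2[r2 == labels[y]] = labels[x]
            c2[c2 == labels[y]] = labels[x]
            gains.append((barber_modularity(a, r2, c2) - base,
                          labels[x], labels[y]))
    gains.sort(key=lambda t: -t[0])
    for gain, keep, drop in gains[:max_trials]:
        r2, c2 = rlab.copy(), clab.copy()
        r2[r2 == drop] = keep
        c2[c2 == drop] = keep
        for _ in range(200):
            if not _lpa_sweep(B, r2, c2, rng):
                break
        if barber_modularity(a, r2, c2) > base + 1e-12:
            rlab[:], clab[:] = r2, c2
            return True
    # split trials: dissolve one module into singletons and re-propagate
    fresh = int(max(rlab.max(), clab.max())) + 1
    for lab in labels[:max_trials]:
        r2, c2 = rlab.copy(), clab.copy()
        nxt = fresh
        for arr in (r2, c2):
            for i in np.flatnonzero(arr == lab):
                arr[i] = nxt
                nxt += 1
        for _ in range(200):
            if not _lpa_sweep(B, r2, c2, rng):
                break
        if barber_modularity(a, r2, c2) > base + 1e-12:
            rlab[:], clab[:] = r2, c2
            return True
    return False


def modularity_lpawb(web, n_restarts: int = 10,
                     seed: int | np.random.Generator | None = None
                     ) -> tuple[float, dict[str, int]]:
    """Maximize Barber modularity by weighted label propagation (LPAwb+).

    Runs ``n_restarts`` independent restarts with randomized sweep orders,
    each alternating label-propagation sweeps with agglomerative module
    merges until Q stops improving, and returns the best (Q, partition).
    Partition keys are ``"r<i>"`` / ``"c<j>"`` for row/column indices.
    """
    a = _as_array(web)
    if _degenerate(a):
        return float("nan"), {}
    rng = np.random.default_rng(seed)
    F = a.sum()
    B = a - np.outer(a.sum(axis=1), a.sum(axis=0)) / F
    R, C = a.shape
    best_q, best_part = -np.inf, (None, None)
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            rlab = np.arange(R)
            clab = np.array([int(np.argmax(a[:, j])) for j in range(C)])
        elif restart % 2 == 1 or best_part[0] is None:
            # diversification: fully random starting partition
            rlab = rng.integers(0, R, size=R)
            clab = rng.integers(0, R, size=C)
        else:
            # intensification: perturb the best partition found so far
            rlab, clab = best_part[0].copy(), best_part[1].copy()
            for arr in (rlab, clab):
                flip = rng.random(arr.shape[0]) < 0.3
                arr[flip] = rng.integers(0, R, size=int(flip.sum()))
        while True:
            for _ in range(200):
                if not _lpa_sweep(B, rlab, clab, rng):
                    break
            if not _agglomerate(a, B, rlab, clab, rng):
                break
        q = barber_modularity(a, rlab, clab)
        if q > best_q:
            best_q, best_part = q, (rlab.copy(), clab.copy())
    rlab, clab = best_part
    relabel: dict[int, int] = {}
    part: dict[str, int] = {}
    for i, lab in enumerate(rlab):
        part[f"r{i}"] = relabel.setdefault(int(lab), len(relabel))
    for j, lab in enumerate(clab):
        part[f"c{j}"] = relabel.setdefault(int(lab), len(relabel))
    return float(best_q), part


# -- full metric set ---------------------------------------------------


@dataclass
class MetricSet:
    h2_prime: float
    interaction_evenness: float
    generality_qual: float
    vulnerability_qual: float
    generality_quant: float
    vulnerability_quant: float
    nodf_qual: float
    nodf_quant: float
    modularity_q: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


METRIC_NAMES = tuple(MetricSet.__dataclass_fields__)


def metric_set(web, seed: int | np.random.Generator | None = None,
               n_restarts: int = 10,
               evenness_denominator: str = "cells",
               metrics: tuple[str, ...] | None = None) -> MetricSet:
    """All network metrics of one web; NaN for degenerate webs.

    ``metrics`` restricts computation to a subset (others NaN), which
    matters when thousands of randomized subwebs are scored.
    """
    want = set(METRIC_NAMES if metrics is None else metrics)
    nan = float("nan")

    def compute(name, fn):
        return fn() if name in want else nan

    return MetricSet(
        h2_prime=compute("h2_prime", lambda: h2_prime(web)),
        interaction_evenness=compute(
            "interaction_evenness",
            lambda: interaction_evenness(web, evenness_denominator)),
        generality_qual=compute(
            "generality_qual", lambda: partner_diversity(web, "rows", weighted=False)),
        vulnerability_qual=compute(
            "vulnerability_qual",
            lambda: partner_diversity(web, "columns", weighted=False)),
        generality_quant=compute(
            "generality_quant", lambda: partner_diversity(web, "rows", weighted=True)),
        vulnerability_quant=compute(
            "vulnerability_quant",
            lambda: partner_diversity(web, "columns", weighted=True)),
        nodf_qual=compute("nodf_qual", lambda: nodf(web, weighted=False)),
        nodf_quant=compute("nodf_quant", lambda: nodf(web, weighted=True)),
        modularity_q=compute(
            "modularity_q", lambda: modularity_lpawb(web, n_restarts, seed)[0]),
    )
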