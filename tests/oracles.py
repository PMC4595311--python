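"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (enumeration,
brute force, closed forms) and shares no code with the package, so a test
comparing package output against these functions is a genuine dual-route
check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


# --------------------------------------------------------------------------
# Forward matching: literal step-by-step simulation


def forward_reference(peaks, tolerance):
    """Transliteration of the forward sliding-window description.

    ``peaks``: list of (spectrum_id, mz) tuples.  Returns a list of clusters,
    each a list of (spectrum_id, mz), in ascending center order.  Peaks are
    visited from minimum to maximum m/z; a peak joins the last-created
    cluster iff |mz - mean(cluster)| <= tolerance, else opens a new cluster.
    A cluster may not hold two peaks of one spectrum: the member whose
    retention minimizes the cluster's mean absolute deviation stays, the
    other peak opens a new cluster.
    """
    pool = sorted(peaks, key=lambda p: (p[1], p[0]))
    clusters = []
    for sid, mz in pool:
        if clusters:
            last = clusters[-1]
            center = sum(m for _, m in last) / len(last)
            if abs(mz - center) <= tolerance:
                dup = [(s, m) for s, m in last if s == sid]
                if not dup:
                    last.append((sid, mz))
                else:
                    rest = [(s, m) for s, m in last if s != sid]

                    def mad(members):
                        c = sum(m for _, m in members) / len(members)
                        return sum(abs(m - c) for _, m in members) / len(members)

                    keep_new = mad(rest + [(sid, mz)]) < mad(rest + dup)
                    if keep_new:
                        clusters[-1] = rest + [(sid, mz)]
                        clusters.append([dup[0]])
                    else:
                        clusters.append([(sid, mz)])
                continue
        clusters.append([(sid, mz)])
    clusters.sort(key=lambda c: sum(m for _, m in c) / len(c))
    return clusters


# --------------------------------------------------------------------------
# Fisher exact test by hypergeometric enumeration


def fisher_enumerate(a, b, c, d):
    """Two-sided Fisher p for [[a, b], [c, d]] by exact enumeration.

    Sums the probabilities of every table with the observed margins whose
    hypergeometric probability is <= the observed one (with the usual tiny
    relative slack for float-free comparison via Fractions).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(min(total, Fraction(1)))


# --------------------------------------------------------------------------
# Exact permutation test (2 conditions)


def _chi2_stat_2x2(n1_present, n1, n2_present, n2):
    """Pearson chi-square of [[n1_present, n1-n1_present], [n2_present, ...]]."""
    total = n1 + n2
    col1 = n1_present + n2_present
    col2 = total - col1
    stat = 0.0
    for row_n, present in ((n1, n1_present), (n2, n2_present)):
        for col_total, obs in ((col1, present), (col2, row_n - present)):
            e = row_n * col_total / total
            if e > 0:
                stat += (obs - e) ** 2 / e
    return stat


def exact_permutation_p(presence, labels):
    """Exact two-condition permutation p-value of the chi-square statistic.

    Enumerates every distinct assignment of the group-1 positions
    (C(n, n1) labelings) and returns the fraction with statistic >= the
    observed one.
    """
    groups = sorted(set(labels))
    assert len(groups) == 2
    n = len(labels)
    idx1 = [i for i, l in enumerate(labels) if l == groups[0]]
    n1 = len(idx1)
    n2 = n - n1
    obs = _chi2_stat_2x2(
        sum(presence[i] for i in idx1), n1,
        sum(presence[i] for i in range(n) if i not in idx1), n2,
    )
    hits = 0
    count = 0
    for combo in itertools.combinations(range(n), n1):
        s1 = sum(presence[i] for i in combo)
        s2 = sum(presence) - s1
        stat = _chi2_stat_2x2(s1, n1, s2, n2)
        count += 1
        if stat >= obs - 1e-12:
            hits += 1
    return hits / count


# --------------------------------------------------------------------------
# BH step-up by the textbook formula


def bh_reference(pvals):
    """q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            pvals[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[i] = min(1.0, min(candidates))
    return q


# --------------------------------------------------------------------------
# Brute-force agglomerative clustering


def brute_force_agglomerate(dist, linkage):
    """O(n^3) agglomerator recomputing every linkage value from scratch.

    ``dist``: full symmetric leaf distance matrix (list of lists).  Returns
    the merge sequence [(height, frozenset(left leaves), frozenset(right
    leaves)), ...] with ties broken by the smallest (min-leaf-left,
    min-leaf-right) pair.
    """
    n = len(dist)
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                pair_d = [dist[i][j] for i in clusters[x] for j in clusters[y]]
                if linkage == "single":
                    d = min(pair_d)
                elif linkage == "complete":
                    d = max(pair_d)
                else:
                    d = sum(pair_d) / len(pair_d)
                a, b = sorted((clusters[x], clusters[y]), key=min)
                key = (d, min(a), min(b))
                if best is None or key < best[0]:
                    best = (key, x, y, a, b)
        (d, _, _), x, y, a, b = best
        merges.append((d, a, b))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(a | b)
        clusters.sort(key=min)
    return merges


# --------------------------------------------------------------------------
# Brute-force maximal all-1 submatrix enumeration


def enumerate_maximal_biclusters(cells, min_rows=1, min_cols=1):
    """All inclusion-maximal all-1 submatrices of a small 0/1 matrix.

    Iterates every nonempty row subset, takes the columns common to those
    rows, expands the row set to every row covering those columns, and
    deduplicates — the classic closure construction, feasible up to ~12
    rows.  Returns a sorted list of (row tuple, col tuple) index pairs.
    """
    n_rows = len(cells)
    n_cols = len(cells[0]) if n_rows else 0
    found = set()
    for r in range(1, n_rows + 1):
        for rows in itertools.combinations(range(n_rows), r):
            cols = tuple(
                j for j in range(n_cols) if all(cells[i][j] for i in rows)
            )
            if not cols:
                continue
            closed_rows = tuple(
                i for i in range(n_rows) if all(cells[i][j] for j in cols)
            )
            found.add((closed_rows, cols))
    return sorted(
        (r, c) for r, c in found if len(r) >= min_rows and len(c) >= min_cols
    )


# --------------------------------------------------------------------------
# AUC by pairwise concordance


def auc_concordance(scores, truth):
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), counted over all pairs."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
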