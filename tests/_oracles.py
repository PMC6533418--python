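"""Independent brute-force oracles for the exact tests and clustering.

Everything here is deliberately written without the package (and without
scipy): plain-python mid-ranks, literal enumeration of sign patterns,
group labelings and permutations, and step-by-step average-linkage
agglomeration. These are the references the implementation is checked
against; keep them simple, not fast.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import sqrt


def midranks(values):
    """Average ranks (1-based) with ties sharing their mean position."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _two_sided(p_low, p_high):
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_exact_p(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = midranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    total = 2**n
    n_low = n_high = 0
    for pattern in range(total):
        w = sum(ranks[i] for i in range(n) if pattern >> i & 1)
        if w <= w_obs + 1e-9:
            n_low += 1
        if w >= w_obs - 1e-9:
            n_high += 1
    return _two_sided(n_low / total, n_high / total)


def mann_whitney_exact_p(a, b):
    """Two-sided exact U-test p by enumerating all group labelings."""
    na = len(a)
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    u_obs = sum(ranks[:na]) - na * (na + 1) / 2.0
    labelings = list(combinations(range(len(pooled)), na))
    n_low = n_high = 0
    for idx in labelings:
        u = sum(ranks[i] for i in idx) - na * (na + 1) / 2.0
        if u <= u_obs + 1e-9:
            n_low += 1
        if u >= u_obs - 1e-9:
            n_high += 1
    total = len(labelings)
    return _two_sided(n_low / total, n_high / total)


def _pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / sqrt(sxx * syy)


def spearman_rho(x, y):
    return _pearson(midranks(x), midranks(y))


def spearman_perm_p(x, y):
    """Two-sided permutation p over all n! pairings of the rank vectors."""
    rx = midranks(x)
    ry = midranks(y)
    rho_obs = abs(_pearson(rx, ry))
    count = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(_pearson(rx, list(perm))) >= rho_obs - 1e-12:
            count += 1
    return count / total


def average_linkage_merges(dist):
    """Brute-force average-linkage agglomeration.

    ``dist``: dict mapping frozenset({i, j}) -> distance over items
    0..n-1. Returns a list of (leafset_a, leafset_b, height) in merge
    order, breaking ties by the lexicographically smallest pair of
    cluster leaf lists.
    """
    items = sorted({i for pair in dist for i in pair})
    clusters = [frozenset([i]) for i in items]

    def avg_dist(c1, c2):
        return sum(dist[frozenset([i, j])] for i in c1 for j in c2) / (
            len(c1) * len(c2)
        )

    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters, key=sorted), 2):
            d = avg_dist(a, b)
            key = (d, sorted(a), sorted(b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((a, b, d))
    return merges
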