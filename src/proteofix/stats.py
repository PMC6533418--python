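"""Small-sample nonparametric statistics with exact p-values.

Paired cohorts of ~16 patients sit exactly where asymptotic p-values are
least trustworthy, so the three tests used throughout — Spearman rank
correlation, the Wilcoxon signed-rank test and the Mann–Whitney U test —
compute *exact* conditional p-values for small n and fall back to the
usual tie-corrected normal / t approximations for larger n:

==================  ======================  ==========================
test                exact method            exact up to (default)
==================  ======================  ==========================
Spearman            all n! permutations     n <= 9
Wilcoxon            2^n sign patterns       n_effective <= 25 (via a
                    (mid-ranks kept fixed)  rank-polynomial convolution)
Mann–Whitney U      all C(n, n_a) group     n_a + n_b <= 12
                    labelings
==================  ======================  ==========================

Conventions (documented choices; they matter at these sample sizes):
zero differences are dropped before signed-ranking; ties receive
mid-ranks; two-sided p = min(1, 2 * min(lower tail, upper tail)), tails
inclusive of the observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "exact"
    ok: bool = True
    note: str = ""


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str = "exact"
    ok: bool = True
    note: str = ""


def _two_sided(p_low: float, p_high: float) -> float:
    return float(min(1.0, 2.0 * min(p_low, p_high)))


# ----------------------------------------------------------- Spearman

def spearman(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with permutation-exact p for small n.

    rho is the Pearson correlation of mid-ranks. For ``n <= exact_max_n``
    the two-sided p is the fraction of all n! permutations of one rank
    vector with |rho| at least the observed |rho|; otherwise the
    t-approximation with n - 2 degrees of freedom is used. Constant input
    yields a flagged (``ok=False``) result rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return CorrelationResult(
            rho=float("nan"), p_value=float("nan"), n=n, method="undefined",
            ok=False, note="constant input: rho undefined",
        )
    rho = float((rxc * ryc).sum() / denom)

    if n <= exact_max_n:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        rho_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return CorrelationResult(rho=rho, p_value=p, n=n, method="exact")
    if abs(rho) >= 1.0:
        return CorrelationResult(
            rho=rho, p_value=float(np.nextafter(0, 1)), n=n,
            method="t_approximation",
        )
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(
        rho=rho, p_value=max(p, np.nextafter(0, 1)), n=n,
        method="t_approximation",
    )


# ------------------------------------------------ Wilcoxon signed-rank

def _signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Null pmf of 2*W+ given doubled integer mid-ranks.

    Equivalent to enumerating all 2^n sign patterns: the distribution of
    the positive-rank sum is the normalized coefficient sequence of
    prod_i (1 + z^{r_i}) with r_i the doubled ranks.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(before, after, exact_max_n: int = 25) -> PairedTestResult:
    """Paired signed-rank test on ``after - before``.

    Zero differences are dropped; |differences| get mid-ranks; W+ is the
    rank sum of positive differences. Exact p (conditional on the observed
    rank multiset) for ``n_effective <= exact_max_n``, else the
    tie-corrected normal approximation without continuity correction.
    All-zero differences yield a flagged degenerate result.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("before and after must have equal length")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult(
            statistic=float("nan"), p_value=float("nan"), n_effective=0,
            method="degenerate", ok=False, note="all differences zero",
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(np.int64)  # mid-ranks double to ints
        pmf = _signed_rank_pmf(ranks2)
        w2 = int(round(2 * w_plus))
        p = _two_sided(pmf[: w2 + 1].sum(), pmf[w2:].sum())
        return PairedTestResult(statistic=w_plus, p_value=p, n_effective=n)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    # counts of tied |d| groups; each group of size t removes (t^3 - t)/48
    tie = float(((counts**3 - counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return PairedTestResult(
        statistic=w_plus, p_value=min(1.0, max(p, np.nextafter(0, 1))),
        n_effective=n, method="normal_approximation",
    )


# ------------------------------------------------------ Mann–Whitney U

def mann_whitney_u(a, b, exact_max_n: int = 12) -> PairedTestResult:
    """Two-sample rank-sum test; U counted for group ``a``.

    Exact p enumerates all C(n, n_a) assignments of the pooled mid-ranks
    when the pooled size is at most ``exact_max_n``; larger samples use
    the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise ValueError(f"both groups must be non-empty (sizes {na}, {nb})")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    n = na + nb

    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        u2_obs = int(round(2 * u))
        idx = np.array(list(combinations(range(n), na)), dtype=np.intp)
        u2_all = ranks2[idx].sum(axis=1) - na * (na + 1)
        total = comb(n, na)
        p = _two_sided(
            float((u2_all <= u2_obs).sum()) / total,
            float((u2_all >= u2_obs).sum()) / total,
        )
        return PairedTestResult(statistic=u, p_value=p, n_effective=n)

    mean = na * nb / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = float((counts**3 - counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie)
    if var == 0:
        return PairedTestResult(
            statistic=u, p_value=1.0, n_effective=n,
            method="normal_approximation", note="all observations tied",
        )
    z = (u - mean) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return PairedTestResult(
        statistic=u, p_value=min(1.0, max(p, np.nextafter(0, 1))),
        n_effective=n, method="normal_approximation",
    )


# --------------------------------------------------------- descriptives

def median_iqr(values) -> tuple[float, float, float, float]:
    """(median, iqr, q1, q3) with linearly interpolated quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of empty input")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1), float(q1), float(q3)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional reporting aid; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
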