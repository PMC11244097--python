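"""Rank-based statistics implemented from first principles.

Tie-safe Spearman correlation, the Mann–Whitney two-sample test and the
Kruskal–Wallis k-sample test, built directly on midranks (tied values
share the average of the ranks they span).  Small untied samples get
exact permutation/enumeration p-values; larger or tied samples use the
tie-corrected large-sample approximations (t for Spearman, normal with
continuity correction for Mann–Whitney, chi-square for Kruskal–Wallis).
All p-values are two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "midranks",
    "spearman",
    "mann_whitney",
    "kruskal_wallis",
    "SpearmanResult",
    "MannWhitneyResult",
    "KruskalWallisResult",
]


def midranks(values) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of the covered ranks."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    method: str


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    return float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))


def spearman(x, y, method: str = "auto") -> SpearmanResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    p-value by exact permutation enumeration for n < 10 (``method='auto'``)
    or by the t approximation t = ρ√((n−2)/(1−ρ²)) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    rx, ry = midranks(x), midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: a variable is constant")
    rho = _rank_corr(rx, ry)

    if method == "auto":
        method = "exact" if n < 10 else "approx"
    if method == "exact":
        # rho is affine in Σ rx·ry(perm) for fixed marginal rank sets, so
        # enumerate the dot-product distribution over all n! pairings
        dx = rx - rx.mean()
        dy = ry - ry.mean()
        denom = np.sqrt(np.dot(dx, dx) * np.dot(dy, dy))
        obs = abs(np.dot(dx, dy))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(np.dot(dx, dy[list(perm)])) >= obs - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sstats.t.sf(abs(tstat), df=n - 2))
        method = "approx"
    return SpearmanResult(rho=rho, pvalue=min(p, 1.0), n=n, method=method)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    pvalue: float
    method: str


def _u_from_ranks(pooled_ranks: np.ndarray, n1: int) -> float:
    r1 = float(pooled_ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(x, y, method: str = "auto") -> MannWhitneyResult:
    """Mann–Whitney U test (U reported for the first sample), two-sided.

    Exact enumeration of all C(n1+n2, n1) group assignments when
    n1+n2 ≤ 12 and there are no ties; tie-corrected normal approximation
    with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    u = _u_from_ranks(ranks, n1)
    has_ties = np.unique(pooled).size < pooled.size
    mid = n1 * n2 / 2.0

    if method == "auto":
        method = "exact" if (n1 + n2 <= 12 and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires untied data")
        obs_dev = abs(u - mid)
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        rk = midranks(pooled)
        for comb in itertools.combinations(idx, n1):
            total += 1
            r1 = float(rk[list(comb)].sum())
            uu = r1 - n1 * (n1 + 1) / 2.0
            if abs(uu - mid) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            dev = abs(u - mid)
            z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity-corrected
            p = 2.0 * float(sstats.norm.sf(z))
        method = "approx"
    return MannWhitneyResult(u=u, pvalue=min(p, 1.0), method=method)


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    pvalue: float
    df: int


def kruskal_wallis(groups) -> KruskalWallisResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square (g−1) p-value."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(gs)
    n = pooled.size
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: H undefined")
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + g.size]
        h += float(r.sum()) ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    h /= correction
    df = len(gs) - 1
    p = float(sstats.chi2.sf(h, df))
    return KruskalWallisResult(h=float(h), pvalue=p, df=df)
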