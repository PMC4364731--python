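"""Statistical kernels: rank-sum test, hypergeometric/Fisher exact test,
and the fold-enrichment statistic.

These are written from first principles (log-space factorials, explicit
enumeration for small exact cases) because their exact conventions — the
minimum-likelihood two-sided Fisher rule, tie-corrected continuity-
corrected rank-sum approximation — are the contract the rest of the
pipeline is specified against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

__all__ = [
    "EnrichmentResult",
    "RankSumResult",
    "fisher_exact_two_sided",
    "fold_enrichment",
    "hypergeom_pmf",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class RankSumResult:
    """Two-sample rank-sum test result.

    w_statistic is the rank-sum of the first sample; z the tie-corrected
    normal deviate (0.0 under the exact method); method is ``exact`` or
    ``normal_approx``.
    """

    w_statistic: float
    z: float
    p_two_sided: float
    method: str


@dataclass(frozen=True)
class EnrichmentResult:
    """Gene-set enrichment of one prioritized gene list.

    m: overlap between the n prioritized genes and the disease set of
    size M drawn from a background of N genes; fold = (m/n)/(M/N).
    """

    m: int
    n: int
    M: int
    N: int
    fold: float
    p_value: float


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _midranks(pooled: Sequence[float]) -> tuple[list[float], list[int]]:
    """Mid-ranks of the pooled sample and the tie-group sizes."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    ties: list[int] = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        ties.append(j - i + 1)
        i = j + 1
    return ranks, ties


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_n_max: int = 8
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Ties receive mid-ranks. When both samples have at most
    ``exact_n_max`` observations and the pooled sample is tie-free, the
    null distribution of the rank-sum W of ``x`` is enumerated over all
    C(n+m, n) assignments of ranks and the two-sided p-value is
    2 * min(P(W <= w), P(W >= w)), capped at 1. Otherwise the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used (the convention of the standard R implementation).
    Two identical samples produce p = 1 with a warning, never an error.
    """
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = list(x) + list(y)
    ranks, ties = _midranks(pooled)
    w = sum(ranks[:n1])
    N = n1 + n2
    has_ties = any(t > 1 for t in ties)

    if len(set(pooled)) == 1:
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return RankSumResult(w, 0.0, 1.0, "normal_approx")

    if not has_ties and n1 <= exact_n_max and n2 <= exact_n_max:
        # enumerate all ways to assign n1 of the N distinct ranks to x
        total = math.comb(N, n1)
        le = ge = 0
        for combo in combinations(range(1, N + 1), n1):
            s = sum(combo)
            if s <= w:
                le += 1
            if s >= w:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return RankSumResult(w, 0.0, p, "exact")

    mean = n1 * (N + 1) / 2.0
    tie_term = sum(t**3 - t for t in ties)
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    if var <= 0:
        warnings.warn("zero rank variance; p = 1", stacklevel=2)
        return RankSumResult(w, 0.0, 1.0, "normal_approx")
    diff = w - mean
    # continuity correction shrinks |diff| by 0.5
    cc = 0.5 if abs(diff) > 0.5 else abs(diff)
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * _norm_sf(abs(z)))
    return RankSumResult(w, z, p, "normal_approx")


# ---------------------------------------------------------------------------
# hypergeometric / Fisher
# ---------------------------------------------------------------------------


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(k: int, n: int, M: int, N: int) -> float:
    """P(X = k) for k successes in a sample of n from a population of N
    containing M successes. Log-space evaluation; exact to ~1e-15 even at
    genome-scale N."""
    if not (0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"impossible margins: n={n}, M={M}, N={N}")
    lo, hi = max(0, n + M - N), min(n, M)
    if k < lo or k > hi:
        return 0.0
    return math.exp(_log_comb(M, k) + _log_comb(N - M, n - k) - _log_comb(N, n))


def fisher_exact_two_sided(m: int, n: int, M: int, N: int) -> float:
    """Two-sided Fisher's exact p-value for overlap ``m`` given margins.

    Minimum-likelihood convention: the p-value sums pmf(k) over every k
    in the support whose probability does not exceed pmf(m) by more than
    a 1e-7 relative slack — the tie-tolerance behaviour of the standard
    R implementation.
    """
    if not (0 <= m <= min(n, M)) or not (0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"impossible margins: m={m}, n={n}, M={M}, N={N}")
    lo, hi = max(0, n + M - N), min(n, M)
    if m < lo:
        raise ValueError(f"m={m} below the support minimum {lo} for these margins")
    p_obs = hypergeom_pmf(m, n, M, N)
    cutoff = p_obs * (1.0 + 1e-7)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf(k, n, M, N)
        if pk <= cutoff:
            total += pk
    return min(1.0, total)


def fold_enrichment(m: int, n: int, M: int, N: int) -> float:
    """Fold enrichment (m/n)/(M/N): the overlap fraction of the n
    prioritized genes in the disease set of size M, relative to the
    background expectation M/N over N genes."""
    if n <= 0 or M <= 0 or N <= 0:
        raise ValueError(f"fold enrichment undefined for n={n}, M={M}, N={N}")
    if m < 0 or m > min(n, M):
        raise ValueError(f"m={m} impossible for n={n}, M={M}")
    return (m / n) / (M / N)
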