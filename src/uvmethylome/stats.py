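"""Nonparametric tests and overlap-significance machinery.

The tests mirror the classical web-calculator conventions used in plant
epigenomics work: Wilcoxon signed-rank (paired window levels, small-RNA
abundances), Mann-Whitney U (chromocenter occupancy groups), chi-square
goodness of fit (region composition), and the representation factor R with a
hypergeometric tail for region-set overlaps.  Exact null distributions are
enumerated for small samples; large samples use the normal approximation with
tie and continuity corrections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "chi_square_gof",
    "representation_factor",
    "bh_adjust",
    "relative_root_growth",
]

#: largest n for which the signed-rank null is enumerated exactly
WILCOXON_EXACT_N = 25
#: largest pooled n for which the Mann-Whitney null is enumerated exactly
MANN_WHITNEY_EXACT_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def _signed_rank_null_pmf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of W+ = sum of positive-signed ranks under the null.

    Midranks (ties) are handled by working on doubled ranks, which are
    integers; the support is returned on the original (halved) scale.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    support = np.arange(total + 1) / 2.0
    return support, pmf


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on (a, b) pairs.

    Differences b−a; zero differences dropped; exact enumeration of the null
    for n ≤ 25 (tie midranks handled exactly), otherwise normal approximation
    with tie and continuity corrections.  All differences zero → p = 1.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("wilcoxon_signed_rank requires at least one pair")
    d = np.asarray([b - a for a, b in pairs], dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "degenerate", (len(pairs),))
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_N:
        support, pmf = _signed_rank_null_pmf(ranks)
        lower = pmf[support <= w_plus + 1e-9].sum()
        upper = pmf[support >= w_plus - 1e-9].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(w_plus, p, "exact", (n,))
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "degenerate", (n,))
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, p, "approximate", (n,))


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group assignments (no ties)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    na = a.size
    u_obs = _u_statistic(a, b)
    lower = upper = total = 0
    idx = range(pooled.size)
    for combo in combinations(idx, na):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs + 1e-9:
            lower += 1
        if u >= u_obs - 1e-9:
            upper += 1
    return min(1.0, 2.0 * min(lower, upper) / total)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a (ties counted half)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact by enumeration when n_a + n_b ≤ 12 and there are no ties; otherwise
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    u = _u_statistic(a, b)
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= MANN_WHITNEY_EXACT_N and no_ties:
        return TestResult(u, _mann_whitney_exact(a, b), "exact", (a.size, b.size))
    na, nb = a.size, b.size
    mean = na * nb / 2.0
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, "degenerate", (na, nb))
    diff = u - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u, p, "approximate", (na, nb))


def chi_square_gof(
    observed: Sequence[float], expected_fractions: Sequence[float]
) -> TestResult:
    """Goodness-of-fit chi-square of observed counts against expected
    fractions, df = k − 1.  Warns when any expected count falls below 5."""
    observed = np.asarray(list(observed), dtype=float)
    fractions = np.asarray(list(expected_fractions), dtype=float)
    if observed.size < 2 or observed.size != fractions.size:
        raise ValueError("need >= 2 matching categories")
    expected = observed.sum() * fractions
    if np.any(expected == 0):
        raise ValueError("expected count of 0 in some category")
    if np.any(expected < 5):
        warnings.warn("chi-square expected count < 5", stacklevel=2)
    stat, p = sps.chisquare(observed, expected)
    return TestResult(float(stat), float(p), "approximate", (int(observed.sum()),))


@dataclass(frozen=True)
class RepresentationFactor:
    R: float
    p_value: float
    p_lower: float | None
    expected: float
    n1: int
    n2: int
    x: int
    N: int


def representation_factor(n1: int, n2: int, x: int, N: int) -> RepresentationFactor:
    """Representation factor R = x / (n1·n2/N) with hypergeometric tail p.

    ``x`` regions shared between groups of sizes ``n1`` and ``n2`` drawn from
    a universe of ``N``; p = P(X ≥ x) under Hypergeometric(N, n1, n2); the
    lower tail P(X ≤ x) is also reported when R < 1.
    """
    if N <= 0:
        raise ValueError("universe N must be positive")
    if x > min(n1, n2) or n1 > N or n2 > N or min(n1, n2, x) < 0:
        raise ValueError(f"inconsistent overlap counts n1={n1} n2={n2} x={x} N={N}")
    expected = n1 * n2 / N
    if expected == 0:
        raise ValueError("expected overlap is 0")
    R = x / expected
    dist = sps.hypergeom(N, n1, n2)
    p_upper = float(dist.sf(x - 1))
    p_lower = float(dist.cdf(x)) if R < 1 else None
    return RepresentationFactor(R, p_upper, p_lower, expected, n1, n2, x, N)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def relative_root_growth(treated_length: float, untreated_length: float) -> float:
    """Relative root growth, percent: (treated / untreated) × 100."""
    if untreated_length <= 0:
        raise ValueError("untreated length must be positive")
    return 100.0 * treated_length / untreated_length
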