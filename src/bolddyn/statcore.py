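"""Statistical primitives shared by the whole pipeline.

Rank tests, correlations, Benjamini-Hochberg FDR and Monte-Carlo permutation
p-values, with the exact conventions the downstream analyses depend on:

* Mann-Whitney U counts pairs ``x_i < y_j`` (first-argument convention), the
  normal z uses no continuity correction, and the exact two-sided p is twice
  the smaller tail of the fully enumerated tie-free null, capped at 1.
* Permutation p-values use the add-one convention ``(1 + #{null >= obs}) / (1 + B)``
  so that a Monte-Carlo p is never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MwuResult",
    "PermutationSpec",
    "mann_whitney",
    "bh_fdr",
    "perm_pvalue",
    "spearman_rho",
    "spearman_test",
    "wilcoxon_signed_rank",
    "pearson_r",
]


@dataclass(frozen=True)
class MwuResult:
    """Result of a two-sided Mann-Whitney U test.

    ``u`` counts pairs with ``x_i < y_j`` (ties contribute 1/2).  ``p_exact``
    is ``None`` when the exact path was not taken (ties present, or the
    group sizes exceed ``exact_limit``); ``tie_warning`` flags a requested
    exact p that fell back to the normal approximation because of ties.
    """

    u: float
    z: float
    p_exact: float | None
    p_normal: float
    n1: int
    n2: int
    tie_warning: bool = False

    @property
    def p(self) -> float:
        """Exact p when available, otherwise the normal-approximation p."""
        return self.p_exact if self.p_exact is not None else self.p_normal


@dataclass(frozen=True)
class PermutationSpec:
    """Number of label shuffles and master seed for a permutation test."""

    n_permutations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of arrangements per U value for tie-free samples of sizes n1, n2.

    Dynamic program on the classic recurrence
    ``f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u)``; the result sums to
    ``C(n1 + n2, n1)``.
    """
    max_u = n1 * n2
    prev = np.zeros((n2 + 1, max_u + 1))
    prev[:, 0] = 1.0  # i = 0: U is 0 for any j
    for _ in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0  # j = 0: U is 0
        for j in range(1, n2 + 1):
            cur[j] = cur[j - 1]
            cur[j, j:] = cur[j, j:] + prev[j, :-j]
        prev = cur
    return prev[n2]


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 25
) -> MwuResult:
    """Two-sided Mann-Whitney U test with both exact and normal p-values.

    U counts pairs ``x_i < y_j`` (ties count 1/2), so a large U means the
    second sample tends to be larger.  The z statistic uses the tie-corrected
    variance and no continuity correction.  The exact p (tie-free data only,
    and only when ``n1 + n2 <= exact_limit``) is twice the smaller tail of the
    enumerated null distribution of U, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r2 = ranks[n1:].sum()
    u = r2 - n2 * (n2 + 1) / 2.0  # pairs with x_i < y_j, ties as 1/2

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        raise ValueError("zero-variance pooled sample (all values tied)")
    z = (u - n1 * n2 / 2.0) / math.sqrt(var_u)
    p_normal = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))

    p_exact: float | None = None
    tie_warning = False
    if n <= exact_limit:
        if has_ties:
            tie_warning = True
        else:
            counts = _exact_u_counts(n1, n2)
            total = counts.sum()
            k = int(round(u))
            lower = counts[: k + 1].sum() / total
            upper = counts[k:].sum() / total
            p_exact = float(min(1.0, 2.0 * min(lower, upper)))
    return MwuResult(float(u), float(z), p_exact, p_normal, n1, n2, tie_warning)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def perm_pvalue(observed: float, null_values: Sequence[float]) -> float:
    """One-sided Monte-Carlo p-value with the add-one convention.

    ``p = (1 + #{null >= observed}) / (1 + B)``; larger statistics are more
    extreme, ties count as at-least-as-extreme (with a small absolute
    tolerance so statistics recomputed through floating-point paths still
    register as ties).
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution must be non-empty")
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + null.size))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties); NaN on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def spearman_test(
    x: Sequence[float], y: Sequence[float], seed: int = 0
) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation p for n <= 8 (full enumeration), seeded Monte-Carlo
    permutation p (B = 20000, add-one on both tails) for 8 < n <= 12, and the
    t approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    if not np.isfinite(rho):
        return rho, float("nan")
    n = x.size
    if n <= 8:
        from itertools import permutations

        ge = tot = 0
        for perm in permutations(range(n)):
            r = stats.spearmanr(x, y[list(perm)]).statistic
            tot += 1
            if abs(r) >= abs(rho) - 1e-12:
                ge += 1
        return rho, ge / tot
    if n <= 12:
        rng = np.random.default_rng(seed)
        b = 20000
        ge = 0
        for _ in range(b):
            r = stats.spearmanr(x, rng.permutation(y)).statistic
            if abs(r) >= abs(rho) - 1e-12:
                ge += 1
        return rho, (1 + ge) / (1 + b)
    return rho, float(stats.spearmanr(x, y).pvalue)


def wilcoxon_signed_rank(x: Sequence[float]) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p for median zero.

    Exact zeros are discarded; at least 5 non-zero values are required.  The
    exact distribution is used for n <= 25 tie-free data, the normal
    approximation otherwise (scipy's "auto" policy).
    """
    x = np.asarray(x, dtype=float)
    nz = x[x != 0]
    if nz.size == 0:
        raise ValueError("all values are zero")
    if nz.size < 5:
        raise ValueError("need >= 5 non-zero values")
    return float(stats.wilcoxon(nz, zero_method="wilcox", mode="auto").pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
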