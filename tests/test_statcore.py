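"""Rank tests, FDR and permutation p-values against hand and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bolddyn.statcore import (
    bh_fdr,
    mann_whitney,
    pearson_r,
    perm_pvalue,
    spearman_rho,
    spearman_test,
    wilcoxon_signed_rank,
)


def _data_with_u(n1: int, n2: int, u: int) -> tuple[np.ndarray, np.ndarray]:
    """Tie-free samples of sizes n1, n2 whose pair count x_i < y_j equals u."""
    # start with complete separation (u = 0) and move y values up one x at a time
    x = np.arange(n2, n2 + n1, dtype=float)
    y = np.arange(n2, dtype=float)
    y[:u // n1] += n1 + n2  # full columns of n1 pairs
    rem = u % n1
    if rem:
        y[u // n1] = x[rem - 1] + 0.5  # sits above exactly rem x values
    return x, y


@pytest.mark.parametrize(
    "u, z_expected, p_exact_expected",
    [(0, -3.10, 7e-4), (8, -2.07, 0.04)],
)
def test_thalamic_loop_comparison_statistics(u, z_expected, p_exact_expected):
    """The loop vs non-loop BCA comparison statistics for group sizes 8 and 6."""
    x, y = _data_with_u(8, 6, u)
    res = mann_whitney(x, y)
    assert res.u == u
    assert round(res.z, 2) == z_expected
    # printed precision: 1 significant figure for 7e-4, 2 decimals for 0.04
    assert res.p == pytest.approx(p_exact_expected, rel=0.2)
    if u == 0:
        assert res.p_exact == pytest.approx(2 / 3003)


def test_mann_whitney_derived_small_case():
    res = mann_whitney([1.0, 2.0], [3.0, 4.0])
    assert res.u == 4
    assert res.p_exact == pytest.approx(1 / 3)


@pytest.mark.parametrize("n1, n2", [(3, 4), (5, 5), (2, 6), (6, 6)])
def test_exact_tail_matches_brute_force(n1, n2, rng):
    """Enumerated U null distribution equals a scan over all assignments."""
    vals = rng.normal(size=n1 + n2)
    res = mann_whitney(vals[:n1], vals[n1:])
    us = []
    for idx in itertools.combinations(range(n1 + n2), n1):
        x = vals[list(idx)]
        y = np.delete(vals, list(idx))
        us.append(np.sum(x[:, None] < y[None, :]))
    us = np.asarray(us)
    expected = min(1.0, 2 * min(np.mean(us <= res.u), np.mean(us >= res.u)))
    assert res.p_exact == pytest.approx(expected, abs=1e-12)


def test_u_antisymmetry_and_scipy_agreement(rng):
    x = rng.normal(size=9)
    y = rng.normal(size=7)
    fwd = mann_whitney(x, y)
    rev = mann_whitney(y, x)
    assert fwd.u + rev.u == 63
    # independent cross-check: scipy counts pairs x > y (+ half ties)
    assert stats.mannwhitneyu(x, y).statistic == pytest.approx(63 - fwd.u)


def test_mann_whitney_tie_fallback_and_errors():
    res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0])
    assert res.tie_warning and res.p_exact is None
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])
    with pytest.raises(ValueError):
        mann_whitney([1.0, 1.0], [1.0, 1.0])


@pytest.mark.parametrize(
    "p_in, expected",
    [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.005, 0.5), (0.01, 0.5)),
        ((0.2,), (0.2,)),
    ],
)
def test_bh_fdr_hand_examples(p_in, expected):
    assert bh_fdr(p_in) == pytest.approx(expected)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bh_fdr_properties(p):
    adj = bh_fdr(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_fdr_rejects_invalid():
    with pytest.raises(ValueError):
        bh_fdr([0.1, 1.5])


def test_perm_pvalue_conventions(rng):
    assert perm_pvalue(10.0, np.zeros(5000)) == pytest.approx(1 / 5001)
    assert perm_pvalue(1.0, [1.0, 1.0, 1.0]) == 1.0
    assert perm_pvalue(0.5, [0.1, 0.9, 0.2]) == 0.5
    null = rng.normal(size=100)
    assert perm_pvalue(0.3, null) == perm_pvalue(0.3, rng.permutation(null))
    with pytest.raises(ValueError):
        perm_pvalue(1.0, [])


def test_spearman_examples():
    x = np.arange(10.0)
    assert spearman_rho(x, 2 * x + 1) == pytest.approx(1.0)
    assert spearman_rho(x, -x) == pytest.approx(-1.0)
    assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
    assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


@given(st.permutations(list(range(8))))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_spearman_monotone_invariance(perm):
    x = np.arange(8.0)
    y = np.asarray(perm, dtype=float)
    rho = spearman_rho(x, y)
    assert spearman_rho(np.exp(x), y) == pytest.approx(rho)
    assert spearman_rho(x, y**3 + 5) == pytest.approx(rho)


def test_spearman_exact_small_n():
    rho, p = spearman_test([1, 2, 3, 4], [1, 3, 2, 4])
    assert rho == pytest.approx(0.8)
    # enumeration over 4! permutations: 8 of 24 have |rho| >= 0.8
    assert p == pytest.approx(8 / 24)


def test_wilcoxon_examples(rng):
    x = np.abs(rng.normal(size=8)) + 0.1
    assert wilcoxon_signed_rank(x) == pytest.approx(2 / 256)
    v = np.r_[1.5, 2.5, 3.5, -1.5, -2.5, -3.5]
    assert wilcoxon_signed_rank(v) == pytest.approx(1.0)
    y = rng.normal(size=20)
    assert wilcoxon_signed_rank(-y) == pytest.approx(wilcoxon_signed_rank(y))
    with pytest.raises(ValueError):
        wilcoxon_signed_rank(np.zeros(10))


def test_pearson_examples():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    assert pearson_r(x, x)[0] == pytest.approx(1.0)
    assert pearson_r(x, -2 * x + 5)[0] == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3], [1, 3, 2])[0] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])
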