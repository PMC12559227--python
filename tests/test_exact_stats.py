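"""Exact-enumeration oracles for the small-sample rank statistics.

Every test here freezes an independently computed null distribution —
exhaustive rank-permutation enumeration for two-group tests, 2^n sign
enumeration for the signed-rank test, n! permutation enumeration for
Spearman — and checks the package's reported p-values against it.
"""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats

from gutshift._exact import (kruskal_exact_two_group, mannwhitney_exact,
                             spearman_exact_p, wilcoxon_exact_p,
                             wilcoxon_normal_p)
from gutshift.correlation import spearman
from gutshift.enrichment import kruskal_gate
from gutshift.responders import baseline_contrast

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_kruskal_p(x, y):
    """Exhaustive two-group Kruskal permutation p via scipy's H statistic."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    h_obs = stats.kruskal(x, y).statistic
    count = total = 0
    for combo in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        h = stats.kruskal(pooled[mask], pooled[~mask]).statistic
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def oracle_mannwhitney_p(x, y):
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    centre = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = total = 0
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
    return count / total


def oracle_wilcoxon_p(diffs):
    """2^n sign-assignment enumeration of the signed-rank statistic."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2.0
    count = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / 2 ** n


# ---------------------------------------------------------------------------
# two-group layouts with <= 8 samples
# ---------------------------------------------------------------------------

LAYOUTS = [(n1, n2) for n1 in range(2, 7) for n2 in range(n1, 7) if n1 + n2 <= 8]


@pytest.mark.parametrize("n1,n2", LAYOUTS)
@pytest.mark.parametrize("ties", [False, True])
def test_kruskal_matches_enumeration(n1, n2, ties):
    rng = np.random.default_rng(n1 * 100 + n2 + int(ties))
    x = rng.integers(0, 4, n1).astype(float) if ties else rng.normal(size=n1)
    y = rng.integers(0, 4, n2).astype(float) if ties else rng.normal(size=n2)
    if np.all(np.concatenate([x, y]) == x[0]):
        x[0] += 1.0
    assert kruskal_exact_two_group(x, y) == pytest.approx(oracle_kruskal_p(x, y),
                                                          abs=1e-12)


@pytest.mark.parametrize("n1,n2", LAYOUTS)
@pytest.mark.parametrize("ties", [False, True])
def test_mannwhitney_matches_enumeration(n1, n2, ties):
    rng = np.random.default_rng(n1 * 1000 + n2 + int(ties))
    x = rng.integers(0, 4, n1).astype(float) if ties else rng.normal(size=n1)
    y = rng.integers(0, 4, n2).astype(float) if ties else rng.normal(size=n2)
    _, p = mannwhitney_exact(x, y)
    assert p == pytest.approx(oracle_mannwhitney_p(x, y), abs=1e-12)


def test_separated_five_vs_five_exact_and_chisquare():
    # exact permutation p for complete separation at 5+5 is 2/252
    x = np.arange(5, dtype=float)
    y = np.arange(10, 15, dtype=float)
    assert kruskal_exact_two_group(x, y) == pytest.approx(2 / 252)
    # at n=10 the gate reports the chi-square approximation (~0.009)
    table = make_table(np.concatenate([x, y])[None, :])
    pvals, passed = kruskal_gate(table, ["a"] * 5 + ["b"] * 5, alpha=0.05)
    assert pvals["f0"] == pytest.approx(stats.kruskal(x, y).pvalue)
    assert 0.008 < pvals["f0"] < 0.010
    assert "f0" in passed


def test_gate_uses_exact_enumeration_at_small_n():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([10.0, 11.0, 12.0, 13.0])
    table = make_table(np.concatenate([x, y])[None, :])
    pvals, _ = kruskal_gate(table, ["a"] * 4 + ["b"] * 4)
    assert pvals["f0"] == pytest.approx(2 / 70)  # C(8,4)=70, two extremes


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_six_positive_pairs_give_two_over_sixtyfour():
    diffs = [1.0, 2.0, 0.5, 3.0, 1.5, 2.5]
    _, p, n = wilcoxon_exact_p(diffs)
    assert n == 6
    assert p == pytest.approx(2 / 64)


def test_mirror_pairs_sit_at_null_centre():
    diffs = [1.0, -1.0, 2.0, -2.0, 3.0, -3.0]
    _, p, _ = wilcoxon_exact_p(diffs)
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
@pytest.mark.parametrize("case", ["plain", "ties", "zeros", "one_negative"])
def test_wilcoxon_matches_sign_enumeration(n, case):
    rng = np.random.default_rng(n * 17 + len(case))
    if case == "plain":
        d = rng.normal(0.5, 1.0, n)
    elif case == "ties":
        d = rng.integers(-3, 4, n).astype(float)
    elif case == "zeros":
        d = rng.normal(0.5, 1.0, n)
        d[:2] = 0.0
    else:
        d = np.abs(rng.normal(1, 0.3, n))
        d[-1] = -0.1
    if np.all(d == 0):
        d[0] = 1.0
    _, p, _ = wilcoxon_exact_p(d)
    assert p == pytest.approx(oracle_wilcoxon_p(d), abs=1e-12)


def test_normal_approximation_close_to_exact_at_moderate_n():
    rng = np.random.default_rng(0)
    d = rng.normal(0.3, 1.0, 22)
    _, p_exact, _ = wilcoxon_exact_p(d)
    _, p_norm, _ = wilcoxon_normal_p(d)
    assert p_norm == pytest.approx(p_exact, abs=0.02)


def test_agrees_with_scipy_exact_when_no_ties():
    rng = np.random.default_rng(4)
    d = rng.normal(0.4, 1.0, 10)
    _, p, _ = wilcoxon_exact_p(d)
    assert p == pytest.approx(stats.wilcoxon(d, method="exact").pvalue)


# ---------------------------------------------------------------------------
# Spearman exact
# ---------------------------------------------------------------------------

def oracle_spearman_p(x, y):
    from itertools import permutations
    y = np.asarray(y, dtype=float)
    rho_obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in permutations(range(len(y))):
        rho = stats.spearmanr(x, y[list(perm)]).statistic
        total += 1
        if abs(rho) >= rho_obs - 1e-12:
            count += 1
    return count / total


@pytest.mark.parametrize("n, ties", [(4, False), (5, False), (5, True),
                                     (6, True)])
def test_spearman_exact_matches_enumeration(n, ties):
    rng = np.random.default_rng(n + 10 * ties)
    x = rng.integers(0, 3, n).astype(float) if ties else rng.normal(size=n)
    y = rng.normal(size=n)
    if len(np.unique(x)) < 2:
        x[0] += 5
    rho, p = spearman(x, y)
    assert p == pytest.approx(oracle_spearman_p(x, y), abs=1e-12)


def test_exact_limit_boundary_monotone_sequence():
    # n = 7 strictly monotone: the only permutations at |rho| = 1 are the
    # identity and the reversal
    rho, p = spearman(range(7), range(7))
    assert rho == 1.0
    assert p == pytest.approx(2 / 5040)


# ---------------------------------------------------------------------------
# Mann-Whitney through baseline_contrast
# ---------------------------------------------------------------------------

def test_contrast_hand_case_exact_p():
    res = baseline_contrast([250, 260, 270], [150, 160, 170])
    assert res.p_raw == pytest.approx(0.1)

def test_contrast_with_ties_matches_enumeration():
    a = [1.0, 2.0, 2.0, 5.0]
    b = [2.0, 3.0, 4.0]
    res = baseline_contrast(a, b)
    assert res.p_raw == pytest.approx(oracle_mannwhitney_p(np.array(a),
                                                           np.array(b)))
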