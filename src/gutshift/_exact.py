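"""Exact small-sample null distributions for the rank tests.

At the cohort sizes this pipeline targets (a handful of subjects per group,
n = 7 responder subgroups), large-sample approximations of rank tests are
unreliable, so the tests switch to exact enumeration below documented size
limits:

* two-group Kruskal-Wallis: enumeration over all C(n, n1) group assignments
  of the pooled values (tie-safe, since H is computed on the actual midranks);
* Mann-Whitney U: same enumeration (used when ties block scipy's exact path);
* Wilcoxon signed-rank: the classic convolution over rank subsets, with
  midranks doubled to integers so ties are handled exactly;
* Spearman: full permutation enumeration of one variable's ranks (n < 10),
  vectorised through a cached permutation-index array.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats

_EPS = 1e-12


def _kruskal_h(ranks: np.ndarray, idx1: np.ndarray, n: int, tie_denom: float
               ) -> float:
    n1 = len(idx1)
    r1 = ranks[idx1].sum()
    r2 = ranks.sum() - r1
    h = 12.0 / (n * (n + 1)) * (r1 * r1 / n1 + r2 * r2 / (n - n1)) - 3 * (n + 1)
    return h / tie_denom if tie_denom > 0 else 0.0


def _tie_denominator(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n) if n > 1 else 1.0


def kruskal_exact_two_group(x, y) -> float:
    """Exact permutation p-value of the two-group Kruskal-Wallis H.

    Enumerates every assignment of the pooled observations into groups of the
    observed sizes; p = fraction of assignments with H >= observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    tie_denom = _tie_denominator(pooled)
    if tie_denom <= 0:  # all values identical
        return 1.0
    h_obs = _kruskal_h(ranks, np.arange(n1), n, tie_denom)
    count = total = 0
    for combo in combinations(range(n), n1):
        total += 1
        if _kruskal_h(ranks, np.array(combo), n, tie_denom) >= h_obs - _EPS:
            count += 1
    return count / total


def mannwhitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration (tie-safe).

    Returns (U of the first group, p).  The two-sided p counts assignments
    whose U is at least as far from the null centre n1*n2/2 as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    n2 = n - n1
    ranks = stats.rankdata(pooled)
    centre = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - centre)
    count = total = 0
    for combo in combinations(range(n), n1):
        total += 1
        u = ranks[np.array(combo)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - centre) >= dev_obs - _EPS:
            count += 1
    return float(u_obs), count / total


def wilcoxon_exact_p(diffs) -> tuple[float, float, int]:
    """Exact two-sided signed-rank p via the rank-sum convolution.

    Zero differences are dropped (Wilcoxon's original policy) before
    ranking.  Midranks from tied |d| are doubled to integers, which leaves
    the sign-flip null distribution exact.  Returns (W+, p, n_after_drop);
    if every difference is zero the result is degenerate: (0, 1.0, 0).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    r2 = np.rint(2 * ranks).astype(int)  # doubled midranks are exact integers
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled W+ == s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r or None]
    counts /= 2.0 ** n
    w2 = int(round(2 * w_plus))
    mean2 = total / 2.0
    dev = abs(w2 - mean2)
    s = np.arange(total + 1)
    p = float(counts[np.abs(s - mean2) >= dev - _EPS].sum())
    return w_plus, min(p, 1.0), n


def wilcoxon_normal_p(diffs) -> tuple[float, float, int]:
    """Signed-rank p from the normal approximation with tie and continuity
    correction; zeros dropped first."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        return w_plus, 1.0, n
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return w_plus, min(p, 1.0), n


@lru_cache(maxsize=8)
def _permutation_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int8 array (n < 10)."""
    from itertools import permutations as iperm
    return np.array(list(iperm(range(n))), dtype=np.int8)


def _standardize_ranks(r: np.ndarray) -> np.ndarray | None:
    r = r - r.mean(axis=-1, keepdims=True)
    norm = np.sqrt((r * r).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = r / norm
    return out


def spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray,
                     rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (n < 10, tie-safe).

    Permutes one variable's midranks against the other's; p = fraction of
    permutations with |rho| >= |rho_obs|.
    """
    n = len(x_ranks)
    perms = _permutation_indices(n)
    xs = _standardize_ranks(np.asarray(x_ranks, dtype=float))
    ys = _standardize_ranks(np.asarray(y_ranks, dtype=float))
    rho_perm = (xs[perms] * ys).sum(axis=1)
    return float((np.abs(rho_perm) >= abs(rho_obs) - _EPS).mean())


def spearman_exact_p_many(cov_ranks: np.ndarray, feat_ranks: np.ndarray,
                          rho_obs: np.ndarray) -> np.ndarray:
    """Vectorised exact Spearman p for one covariate against many features.

    cov_ranks: (n,) midranks of the covariate; feat_ranks: (F, n) midranks of
    each feature; rho_obs: (F,) observed correlations.
    """
    n = cov_ranks.shape[0]
    perms = _permutation_indices(n)
    cs = _standardize_ranks(np.asarray(cov_ranks, dtype=float))
    fs = _standardize_ranks(np.asarray(feat_ranks, dtype=float))
    rho_perm = cs[perms] @ fs.T  # (n!, F)
    return (np.abs(rho_perm) >= np.abs(rho_obs)[None, :] - _EPS).mean(axis=0)
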