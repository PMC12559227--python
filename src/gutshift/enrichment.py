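"""Kruskal + LDA differential enrichment, and the paired signed-rank test.

The differential-enrichment procedure is a two-stage LEfSe-style screen:

1. a Kruskal-Wallis gate flags features whose abundance differs between the
   two groups (p < alpha, default 0.05);
2. a linear-discriminant effect size is computed for each flagged feature:
   abundances are total-sum scaled to 1e6 per sample, a two-class LDA
   direction w is fit on the flagged features (within-class scatter with a
   small ridge, w unit-normalised), and each feature's score is the absolute
   difference of the class means of its component along w, floored at 1 and
   reported as a signed log10.  The sign is + when the feature's mean is
   larger in the second (``positive``) group.

A feature is called enriched when it passes the gate *and* |score| meets the
LDA threshold (default 2.0, i.e. a class-mean separation of at least 100
counts-per-million along the discriminant).  No multiple-testing correction
is applied inside this screen — the correlation screens, by contrast, always
correct.  An optional bootstrap mode averages the score over B rounds of 2/3
subsampling for compatibility with the original LEfSe procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exact import kruskal_exact_two_group, wilcoxon_exact_p, wilcoxon_normal_p
from .profiles import ProfileTable, SampleRecord, Timepoint

__all__ = [
    "EnrichmentResult", "PairedTestResult",
    "kruskal_gate", "lda_effect_size", "lefse", "paired_wilcoxon",
]

#: Two-group totals at or below this size use exact permutation enumeration
#: for the Kruskal gate; above it, the chi-square approximation.
KRUSKAL_EXACT_LIMIT = 8

#: Pair counts at or below this size use the exact signed-rank distribution.
WILCOXON_EXACT_LIMIT = 25

#: Relative ridge on the within-class scatter diagonal (times its mean
#: diagonal) so singular scatters stay solvable at cpm scale.
LDA_RIDGE = 1e-6

LEFSE_NORMALIZATION_TOTAL = 1e6


@dataclass
class EnrichmentResult:
    feature_id: str
    enriched_group: str | None
    kruskal_p: float
    lda_score: float  # signed log10 effect size; NaN if the gate failed
    significant: bool


@dataclass
class PairedTestResult:
    feature_id: str
    n_pairs: int  # pairs remaining after zero differences are dropped
    statistic: float
    p_value: float
    direction: str  # "increase" | "decrease"
    degenerate: bool = False


def _group_arrays(table: ProfileTable, labels) -> tuple[list[str], np.ndarray]:
    if isinstance(labels, dict):
        labels = [labels[s] for s in table.sample_ids]
    labels = list(labels)
    if len(labels) != table.n_samples:
        raise ValueError("one group label per sample required")
    groups = sorted(set(labels))
    codes = np.array([groups.index(l) for l in labels])
    return groups, codes


def kruskal_gate(table: ProfileTable, labels, alpha: float = 0.05,
                 exact_limit: int = KRUSKAL_EXACT_LIMIT
                 ) -> tuple[dict[str, float], set[str]]:
    """Per-feature Kruskal-Wallis p-values and the set passing p < alpha.

    A feature constant across all samples carries no signal and is assigned
    p = 1.  For two groups with total n <= ``exact_limit`` the p-value is the
    exact permutation tail of H; otherwise scipy's tie-corrected chi-square
    approximation is used.
    """
    groups, codes = _group_arrays(table, labels)
    if len(groups) < 2:
        raise ValueError("kruskal_gate needs at least 2 groups")
    values = table.values
    n = values.shape[1]
    use_exact = len(groups) == 2 and n <= exact_limit
    pvals: dict[str, float] = {}
    for i, fid in enumerate(table.feature_ids):
        row = values[i]
        if np.all(row == row[0]):
            pvals[fid] = 1.0
            continue
        samples = [row[codes == g] for g in range(len(groups))]
        if use_exact:
            pvals[fid] = kruskal_exact_two_group(samples[0], samples[1])
        else:
            pvals[fid] = float(stats.kruskal(*samples).pvalue)
    passed = {fid for fid, p in pvals.items() if p < alpha}
    return pvals, passed


def _lefse_normalize(table: ProfileTable) -> ProfileTable:
    """Per-sample total-sum scaling to 1e6 over all features.

    A single-feature table is left on its input scale: closing a
    one-dimensional composition would map every sample to the same value
    and erase the signal.
    """
    if table.n_features < 2:
        return table
    return table.renormalize(LEFSE_NORMALIZATION_TOTAL)


def _lda_direction(x: np.ndarray, y01: np.ndarray, ridge: float) -> np.ndarray:
    """Unit-norm two-class LDA direction from ridge-regularised scatter.

    x: samples x features (already normalised), y01: 0/1 class codes.
    """
    x0, x1 = x[y01 == 0], x[y01 == 1]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    sw = np.zeros((x.shape[1], x.shape[1]))
    for xg, mug in ((x0, mu0), (x1, mu1)):
        c = xg - mug
        sw += c.T @ c
    lam = ridge * max(np.trace(sw) / sw.shape[0], 1.0)
    sw[np.diag_indices_from(sw)] += lam
    w = np.linalg.solve(sw, mu1 - mu0)
    norm = np.linalg.norm(w)
    if norm == 0:
        return w
    return w / norm


def lda_effect_size(table: ProfileTable, labels, pass_set,
                    positive_group: str | None = None,
                    ridge: float = LDA_RIDGE,
                    bootstrap: int = 0, seed: int = 0) -> dict[str, float]:
    """Signed log10 LDA effect size for each feature in ``pass_set``.

    ``positive_group`` names the group given the + sign (default: the
    lexicographically second group, i.e. "post" beats "pre").  With
    ``bootstrap`` = B > 0, the score is averaged over B rounds of
    class-stratified 2/3 subsampling (original-LEfSe compatibility mode).
    """
    groups, codes = _group_arrays(table, labels)
    if len(groups) != 2:
        raise ValueError("LDA effect size is defined for exactly 2 groups")
    if positive_group is None:
        positive_group = groups[1]
    elif positive_group not in groups:
        raise ValueError(f"positive_group {positive_group!r} not among {groups}")
    pos = groups.index(positive_group)
    y01 = (codes == pos).astype(int)
    if (y01 == 0).sum() < 2 or (y01 == 1).sum() < 2:
        raise ValueError("each group needs at least 2 samples for LDA")

    pass_list = [f for f in table.feature_ids if f in set(pass_set)]
    if not pass_list:
        return {}
    norm = _lefse_normalize(table)
    x_all = norm.data.loc[pass_list].to_numpy(dtype=float).T  # samples x passed

    def scores_for(idx: np.ndarray) -> np.ndarray:
        x, y = x_all[idx], y01[idx]
        w = _lda_direction(x, y, ridge)
        delta = x[y == 1].mean(axis=0) - x[y == 0].mean(axis=0)
        effect = np.abs(w * delta)
        return np.sign(delta) * np.log10(np.maximum(effect, 1.0))

    if bootstrap and bootstrap > 0:
        rng = np.random.default_rng(seed)
        acc = np.zeros(len(pass_list))
        rounds = 0
        idx0 = np.flatnonzero(y01 == 0)
        idx1 = np.flatnonzero(y01 == 1)
        for _ in range(bootstrap):
            take0 = rng.choice(idx0, size=max(2, int(round(len(idx0) * 2 / 3))),
                               replace=False)
            take1 = rng.choice(idx1, size=max(2, int(round(len(idx1) * 2 / 3))),
                               replace=False)
            acc += scores_for(np.concatenate([take0, take1]))
            rounds += 1
        s = acc / rounds
    else:
        s = scores_for(np.arange(len(y01)))
    return dict(zip(pass_list, s))


def lefse(table: ProfileTable, labels, alpha: float = 0.05,
          lda_threshold: float = 2.0, positive_group: str | None = None,
          bootstrap: int = 0, seed: int = 0,
          ridge: float = LDA_RIDGE) -> list[EnrichmentResult]:
    """Kruskal gate then LDA effect size; one result per feature.

    Features passing the gate are sorted by |lda_score| descending; gate
    failures follow, sorted by p then id, with lda_score = NaN.  ``significant``
    requires both the gate (p < alpha) and |lda_score| >= lda_threshold.
    """
    groups, codes = _group_arrays(table, labels)
    if len(groups) != 2:
        raise ValueError("lefse is defined for exactly 2 groups")
    if positive_group is None:
        positive_group = groups[1]
    pvals, passed = kruskal_gate(table, labels, alpha=alpha)
    scores = lda_effect_size(table, labels, passed, positive_group=positive_group,
                             ridge=ridge, bootstrap=bootstrap, seed=seed)

    # enriched group = group with the larger mean of the normalised feature
    norm = _lefse_normalize(table)
    x = norm.values
    means = {g: x[:, codes == gi].mean(axis=1) for gi, g in enumerate(groups)}
    results: list[EnrichmentResult] = []
    for i, fid in enumerate(table.feature_ids):
        if fid in scores:
            score = scores[fid]
            enriched = max(groups, key=lambda g: means[g][i])
            sig = pvals[fid] < alpha and abs(score) >= lda_threshold
        else:
            score, enriched, sig = float("nan"), None, False
        results.append(EnrichmentResult(fid, enriched, pvals[fid], score, sig))
    results.sort(key=lambda r: (not np.isfinite(r.lda_score),
                                -abs(r.lda_score) if np.isfinite(r.lda_score) else r.kruskal_p,
                                r.feature_id))
    return results


def paired_wilcoxon(table: ProfileTable, metadata: list[SampleRecord],
                    feature_id: str,
                    exact_limit: int = WILCOXON_EXACT_LIMIT) -> PairedTestResult:
    """Wilcoxon signed-rank test on a feature's within-subject post-pre change.

    Differences are taken over subjects with both timepoints; zero
    differences are dropped before ranking.  Exact two-sided p for
    n_pairs <= ``exact_limit``, normal approximation with tie/continuity
    correction above.  If every difference is zero the result is degenerate
    with p = 1.
    """
    if feature_id not in table.data.index:
        raise KeyError(f"feature {feature_id!r} not in table")
    ids = set(table.sample_ids)
    by_subject: dict[str, dict[str, str]] = {}
    for r in metadata:
        if r.sample_id in ids:
            by_subject.setdefault(r.subject_id, {})[r.timepoint.value] = r.sample_id
    row = table.data.loc[feature_id]
    diffs = []
    for subject in sorted(by_subject):
        tps = by_subject[subject]
        if Timepoint.PRE.value in tps and Timepoint.POST.value in tps:
            diffs.append(row[tps[Timepoint.POST.value]] - row[tps[Timepoint.PRE.value]])
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) == 0:
        raise ValueError("no matched pre/post pairs available")
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return PairedTestResult(feature_id, 0, 0.0, 1.0, "increase",
                                degenerate=True)
    if len(nonzero) <= exact_limit:
        w, p, n = wilcoxon_exact_p(diffs)
    else:
        w, p, n = wilcoxon_normal_p(diffs)
    direction = "increase" if np.median(nonzero) > 0 or (
        np.median(nonzero) == 0 and nonzero.mean() > 0) else "decrease"
    return PairedTestResult(feature_id, n, w, p, direction)
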