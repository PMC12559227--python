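"""Responder stratification: who changed, and how the groups differed at baseline.

Subjects are split by the magnitude of their within-subject (matched)
Bray-Curtis distance: at or above the threshold -> ``large_shift``, below ->
``small_shift``.  The threshold defaults to the cohort median of the matched
distances (the boundary is inclusive, so a subject exactly at the median is a
large-shift responder); an explicit threshold, such as a previously realized
cohort cut of 0.36, can override the median.

Baseline contrasts between the two groups (richness, nutrient intakes, ...)
default to the exact Mann-Whitney U test — group sizes here are single-digit —
with Benjamini-Hochberg adjustment across the variable family when several
variables are contrasted together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exact import mannwhitney_exact
from .beta import MatchedDistanceRecord
from .correlation import bh_adjust
from .enrichment import EnrichmentResult, lefse
from .profiles import ProfileTable, SampleRecord, Timepoint

__all__ = [
    "ResponderLabel", "GroupContrastResult",
    "classify_responders", "baseline_contrast", "contrast_family",
    "baseline_enrichment",
]

LARGE, SMALL = "large_shift", "small_shift"


@dataclass
class ResponderLabel:
    subject_id: str
    distance: float
    group: str  # large_shift | small_shift
    threshold_used: float


@dataclass
class GroupContrastResult:
    variable: str
    group_means: tuple[float, float]  # (large_shift, small_shift)
    statistic: float
    p_raw: float
    q_bh: float
    significant_raw: bool
    significant_adjusted: bool
    degenerate: bool = False


def classify_responders(matched: list[MatchedDistanceRecord],
                        threshold: float | None = None) -> list[ResponderLabel]:
    """Median split (or explicit threshold) on matched distances."""
    if not matched:
        raise ValueError("no matched distances to classify")
    if len(matched) < 2 and threshold is None:
        raise ValueError("need at least 2 subjects for a median split")
    distances = np.array([m.distance for m in matched], dtype=float)
    thr = float(np.median(distances)) if threshold is None else float(threshold)
    return [
        ResponderLabel(m.subject_id, float(m.distance),
                       LARGE if m.distance >= thr else SMALL, thr)
        for m in matched
    ]


#: Mann-Whitney switches from scipy's exact distribution to the asymptotic
#: normal approximation above this combined sample size; tied small samples
#: use in-package enumeration instead (scipy's exact path ignores ties).
MANNWHITNEY_EXACT_LIMIT = 20
_MW_TIE_ENUM_LIMIT = 14


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    if n <= MANNWHITNEY_EXACT_LIMIT:
        if has_ties and n <= _MW_TIE_ENUM_LIMIT:
            return mannwhitney_exact(a, b)
        method = "asymptotic" if has_ties else "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def baseline_contrast(values_large, values_small, method: str = "mann_whitney",
                      variable: str = "value", alpha: float = 0.05
                      ) -> GroupContrastResult:
    """Two-sample contrast of one variable between responder groups.

    With constant pooled data the contrast is degenerate and p = 1.
    ``q_bh`` equals the raw p for a single variable; use
    :func:`contrast_family` to adjust across a family.
    """
    a = np.asarray(values_large, dtype=float)
    b = np.asarray(values_small, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 finite values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return GroupContrastResult(variable, (float(a.mean()), float(b.mean())),
                                   0.0, 1.0, 1.0, False, False, degenerate=True)
    if method == "mann_whitney":
        statistic, p = _mannwhitney_p(a, b)
    elif method == "t_test":
        res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown contrast method {method!r}")
    return GroupContrastResult(variable, (float(a.mean()), float(b.mean())),
                               statistic, p, p, p < alpha, p < alpha)


def contrast_family(variables: dict[str, tuple[list, list]],
                    method: str = "mann_whitney", alpha: float = 0.05
                    ) -> list[GroupContrastResult]:
    """Contrast several variables and BH-adjust across the family.

    ``variables`` maps variable name -> (large-shift values, small-shift
    values).  Degenerate (constant) variables are excluded from the BH family
    but still reported with p = q = 1.
    """
    results = [baseline_contrast(a, b, method=method, variable=name, alpha=alpha)
               for name, (a, b) in variables.items()]
    live = [r for r in results if not r.degenerate]
    if live:
        qs = bh_adjust([r.p_raw for r in live])
        for r, q in zip(live, qs):
            r.q_bh = float(q)
            r.significant_adjusted = r.q_bh < alpha
    return results


def baseline_enrichment(table: ProfileTable, metadata: list[SampleRecord],
                        labels: list[ResponderLabel], alpha: float = 0.05,
                        lda_threshold: float = 2.0, **kwargs
                        ) -> list[EnrichmentResult]:
    """LEfSe contrast of pre-expedition samples between responder groups."""
    group_by_subject = {l.subject_id: l.group for l in labels}
    pre_samples, groups = [], []
    for r in metadata:
        if r.timepoint == Timepoint.PRE and r.subject_id in group_by_subject \
                and r.sample_id in set(table.sample_ids):
            pre_samples.append(r.sample_id)
            groups.append(group_by_subject[r.subject_id])
    counts = {g: groups.count(g) for g in set(groups)}
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("each responder group needs at least 2 baseline samples")
    sub = table.subset_samples(pre_samples)
    # + sign marks enrichment in the large-shift group
    return lefse(sub, groups, alpha=alpha, lda_threshold=lda_threshold,
                 positive_group=LARGE, **kwargs)
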