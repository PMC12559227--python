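"""BH-corrected Spearman screens of features against continuous covariates.

Each invocation of :func:`screen` is one Benjamini-Hochberg family: every
(feature x covariate) pair tested in that call — per timepoint, per data
block, per subject subset — is corrected together, and degenerate pairs
(constant feature or covariate, or fewer than 3 complete pairs) are excluded
before correction.  Missing covariates are handled pairwise-complete, with n
recorded per pair.

Spearman rho is Pearson on midranks (tie-safe).  The p-value uses exact
permutation enumeration below n = 10 — the responder-subgroup screens run at
n = 7, where the t approximation is unreliable — and the t approximation at
n >= 10, matching the conventional scipy behaviour at those sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exact import spearman_exact_p, spearman_exact_p_many
from .profiles import ProfileTable, SampleRecord, Timepoint

__all__ = ["CorrelationResult", "spearman", "screen", "bh_adjust"]

SPEARMAN_EXACT_LIMIT = 10  # exact permutation p strictly below this n


@dataclass
class CorrelationResult:
    feature_id: str
    covariate: str
    timepoint: str
    n: int
    rho: float
    p_raw: float
    q_bh: float
    significant: bool


class DegenerateCorrelation(ValueError):
    """Constant input: Spearman rho undefined."""


def _rank_standardize(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    r = r - r.mean()
    norm = np.sqrt((r * r).sum())
    if norm == 0:
        raise DegenerateCorrelation("constant vector: rho undefined")
    return r / norm


def spearman(x, y, exact_limit: int = SPEARMAN_EXACT_LIMIT
             ) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value.

    Raises :class:`DegenerateCorrelation` on constant input (such pairs are
    excluded from BH families upstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xs, ys = _rank_standardize(x), _rank_standardize(y)
    rho = float(np.clip((xs * ys).sum(), -1.0, 1.0))
    if n < exact_limit:
        p = spearman_exact_p(stats.rankdata(x), stats.rankdata(y), rho)
    else:
        p = _spearman_t_p(rho, n)
    return rho, float(p)


def _spearman_t_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen(table: ProfileTable, metadata: list[SampleRecord],
           covariates: list[str], timepoint: str | Timepoint,
           subjects: list[str] | None = None, alpha: float = 0.05,
           exact_limit: int = SPEARMAN_EXACT_LIMIT) -> list[CorrelationResult]:
    """Spearman screen of every (feature, covariate) pair at one timepoint.

    ``subjects`` restricts the screen to a subset (e.g. the large-shift
    responder group).  All testable pairs form one BH family; results are
    sorted by q, then |rho| descending, then ids.
    """
    if not covariates:
        raise ValueError("empty covariate list")
    tp = Timepoint(timepoint)
    keep = [r for r in metadata
            if r.timepoint == tp and r.sample_id in set(table.sample_ids)
            and (subjects is None or r.subject_id in set(subjects))]
    if len(keep) < 3:
        raise ValueError(f"fewer than 3 samples at timepoint {tp.value!r}")
    sample_ids = [r.sample_id for r in keep]
    x = table.data[sample_ids].to_numpy(dtype=float)  # features x samples

    results: list[CorrelationResult] = []
    for cov in covariates:
        cvals = np.array([r.covariates.get(cov, np.nan) for r in keep])
        results.extend(_screen_one_covariate(
            table.feature_ids, x, cov, cvals, tp.value, exact_limit))
    live = [r for r in results if np.isfinite(r.p_raw)]
    if live:
        qs = bh_adjust([r.p_raw for r in live])
        for r, q in zip(live, qs):
            r.q_bh = float(q)
            r.significant = r.q_bh < alpha
    results.sort(key=lambda r: (not np.isfinite(r.q_bh),
                                r.q_bh if np.isfinite(r.q_bh) else 1.0,
                                -abs(r.rho) if np.isfinite(r.rho) else 0.0,
                                r.feature_id, r.covariate))
    return results


def _screen_one_covariate(feature_ids, x: np.ndarray, cov: str,
                          cvals: np.ndarray, tp: str, exact_limit: int
                          ) -> list[CorrelationResult]:
    mask = np.isfinite(cvals)
    n = int(mask.sum())
    out: list[CorrelationResult] = []
    if n < 3 or len(np.unique(cvals[mask])) < 2:
        # covariate unusable: every pair degenerate
        return [CorrelationResult(f, cov, tp, n, np.nan, np.nan, np.nan, False)
                for f in feature_ids]
    xm = x[:, mask]
    const = np.all(xm == xm[:, :1], axis=1)
    live_idx = np.flatnonzero(~const)
    for i in np.flatnonzero(const):
        out.append(CorrelationResult(feature_ids[i], cov, tp, n,
                                     np.nan, np.nan, np.nan, False))
    if len(live_idx) == 0:
        return out
    feat_ranks = np.apply_along_axis(stats.rankdata, 1, xm[live_idx])
    cov_ranks = stats.rankdata(cvals[mask])
    fs = feat_ranks - feat_ranks.mean(axis=1, keepdims=True)
    fs /= np.sqrt((fs * fs).sum(axis=1, keepdims=True))
    cs = cov_ranks - cov_ranks.mean()
    cs /= np.sqrt((cs * cs).sum())
    rhos = np.clip(fs @ cs, -1.0, 1.0)
    if n < exact_limit:
        ps = spearman_exact_p_many(cov_ranks, feat_ranks, rhos)
    else:
        ps = np.array([_spearman_t_p(r, n) for r in rhos])
    for i, rho, p in zip(live_idx, rhos, ps):
        out.append(CorrelationResult(feature_ids[i], cov, tp, n,
                                     float(rho), float(p), float(p), False))
    return out


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
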