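"""Bray-Curtis beta diversity, matched within-subject distances, PERMANOVA.

The within-subject (matched) distance — Bray-Curtis between the pre- and
post-intervention sample of the same participant — is the quantity the
responder stratification is built on.  PERMANOVA follows Anderson's
distance-based formulation with the add-one permutation p-value estimator
p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), so p is never 0 and is
fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiles import ProfileTable, SampleRecord, Timepoint

__all__ = [
    "bray_curtis", "DistanceMatrix", "distance_matrix",
    "MatchedDistanceRecord", "matched_distances",
    "PermanovaResult", "permanova",
]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero: Bray-Curtis undefined")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal sample-by-sample distance matrix."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


def distance_matrix(table: ProfileTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis on renormalized sample columns.

    Columns are renormalized to a common total first so that taxon (percent)
    and pathway (cpm) tables behave identically — Bray-Curtis on unequal
    totals would conflate depth with composition.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    norm = table.renormalize()  # raises naming the sample on a zero column
    x = norm.values.T  # samples x features
    d = squareform(pdist(x, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(norm.sample_ids, d)


@dataclass
class MatchedDistanceRecord:
    subject_id: str
    distance: float


def matched_distances(dm: DistanceMatrix, metadata: list[SampleRecord]
                      ) -> tuple[list[MatchedDistanceRecord], list[str]]:
    """Within-subject pre-vs-post distances.

    Returns one record per subject having both timepoints in the matrix, plus
    a skip report of subjects missing a timepoint (e.g. a rejected sample).
    """
    ids = set(dm.sample_ids)
    by_subject: dict[str, dict[str, str]] = {}
    for r in metadata:
        if r.sample_id not in ids:
            continue
        tps = by_subject.setdefault(r.subject_id, {})
        if r.timepoint.value in tps:
            raise ValueError(f"subject {r.subject_id!r} has two samples at "
                             f"timepoint {r.timepoint.value!r}")
        tps[r.timepoint.value] = r.sample_id
    records: list[MatchedDistanceRecord] = []
    skipped: list[str] = []
    for subject in sorted(by_subject):
        tps = by_subject[subject]
        if Timepoint.PRE.value in tps and Timepoint.POST.value in tps:
            d = dm[tps[Timepoint.PRE.value], tps[Timepoint.POST.value]]
            records.append(MatchedDistanceRecord(subject, d))
        else:
            skipped.append(subject)
    return records, skipped


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int


def _pseudo_f_terms(d2: np.ndarray, codes: np.ndarray, n_groups: int
                    ) -> tuple[float, float]:
    """(SS_total, SS_within) for squared distances d2 and integer labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def permanova(dm: DistanceMatrix, labels, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``labels`` maps each sample (in matrix order, or as a dict by sample id)
    to a group.  Significance comes from full label permutations; the
    permuted statistics are computed vectorised so the default 999
    permutations cost milliseconds.
    """
    if isinstance(labels, dict):
        labels = [labels[s] for s in dm.sample_ids]
    labels = list(labels)
    n = len(dm.sample_ids)
    if len(labels) != n:
        raise ValueError("one label per sample required")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    codes = np.array([groups.index(l) for l in labels])
    sizes = np.bincount(codes, minlength=len(groups))
    if (sizes < 2).any():
        small = groups[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    k = len(groups)
    d2 = dm.d ** 2

    ss_total, ss_within = _pseudo_f_terms(d2, codes, k)
    df_among, df_within = k - 1, n - k
    f_obs = ((ss_total - ss_within) / df_among) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    # SS_within per permutation: for each group g, sum of d2 over within-group
    # pairs via masked matmul, all permutations at once.
    ssw = np.zeros(n_permutations)
    for g in range(k):
        m = (perms == g).astype(float)  # (P, n)
        ssw += np.einsum("pi,pi->p", m @ d2, m) / (2.0 * sizes[g])
    f_perm = ((ss_total - ssw) / df_among) / (ssw / df_within)
    exceed = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed, n, k)
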