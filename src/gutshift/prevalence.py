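"""Feature prevalence before/after and the low/mid/high prevalence bands.

Prevalence of a feature in a timepoint group is the fraction of that group's
retained samples in which the feature is detected (abundance strictly above
the threshold, default 0).  Denominators are per-timepoint retained sample
counts — they differ when samples were dropped — and both are reported.
Bands encode the "present in less than a third of individuals" reading:
low is prevalence < 1/3, high is > 2/3, mid in between (cut points closed
on the low side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import ProfileTable, SampleRecord, Timepoint

__all__ = ["PrevalenceRecord", "prevalence_table", "top_prevalence_shifts"]


@dataclass
class PrevalenceRecord:
    feature_id: str
    prevalence_pre: float
    prevalence_post: float
    delta: float
    band_pre: str  # low | mid | high
    n_pre: int
    n_post: int


def _band(p: float) -> str:
    if p < 1 / 3:
        return "low"
    if p > 2 / 3:
        return "high"
    return "mid"


def prevalence_table(table: ProfileTable, metadata: list[SampleRecord],
                     threshold: float = 0.0) -> list[PrevalenceRecord]:
    """One prevalence record per feature, pre vs post."""
    ids = set(table.sample_ids)
    pre = [r.sample_id for r in metadata
           if r.sample_id in ids and r.timepoint == Timepoint.PRE]
    post = [r.sample_id for r in metadata
            if r.sample_id in ids and r.timepoint == Timepoint.POST]
    if not pre or not post:
        missing = "pre" if not pre else "post"
        raise ValueError(f"no samples at timepoint {missing!r}")
    x_pre = table.data[pre].to_numpy(dtype=float)
    x_post = table.data[post].to_numpy(dtype=float)
    p_pre = (x_pre > threshold).mean(axis=1)
    p_post = (x_post > threshold).mean(axis=1)
    return [
        PrevalenceRecord(fid, float(a), float(b), float(b - a), _band(float(a)),
                         len(pre), len(post))
        for fid, a, b in zip(table.feature_ids, p_pre, p_post)
    ]


def top_prevalence_shifts(records: list[PrevalenceRecord], k: int
                          ) -> list[PrevalenceRecord]:
    """The k records with the largest |delta|; ties broken by feature id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(records, key=lambda r: (-abs(r.delta), r.feature_id))
    return ranked[:k]


def prevalence_frame(records: list[PrevalenceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("feature_id")
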