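"""Alpha diversity: Shannon entropy, Gini-Simpson, and species richness.

Indices are computed per sample on whatever abundance scale the table carries
(all three are scale-invariant or threshold-based, so percent vs cpm does not
matter).  Shannon is reported in nats by default; ``base`` switches the
logarithm.  "Simpson" here is the Gini-Simpson index 1 - sum(p^2); the
dominance form sum(p^2) and the inverse form 1/sum(p^2) are available via
``variant``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import ProfileTable

__all__ = ["shannon", "simpson", "richness", "alpha_diversity_table"]


def _proportions(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector: diversity undefined")
    return x / total


def shannon(abundances, base: float | None = None) -> float:
    """Shannon entropy H = -sum(p_i log p_i) over positive entries.

    Natural log (nats) unless ``base`` is given.
    """
    p = _proportions(abundances)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    # clamp the -0.0 of a single-species sample
    return 0.0 if h < 0 and h > -1e-15 else h


def simpson(abundances, variant: str = "gini") -> float:
    """Simpson diversity of one sample.

    variant="gini" (default): 1 - sum(p^2), in [0, 1).
    variant="dominance": sum(p^2).  variant="inverse": 1 / sum(p^2).
    """
    p = _proportions(abundances)
    d = float((p * p).sum())
    if variant == "gini":
        return 1.0 - d
    if variant == "dominance":
        return d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant {variant!r}")


def richness(abundances, threshold: float = 0.0) -> int:
    """Number of features with abundance strictly greater than ``threshold``."""
    x = np.asarray(abundances, dtype=float)
    return int((x > threshold).sum())


def alpha_diversity_table(table: ProfileTable, threshold: float = 0.0,
                          base: float | None = None,
                          simpson_variant: str = "gini") -> pd.DataFrame:
    """One row per sample: shannon, simpson, richness."""
    rows = []
    for sid in table.sample_ids:
        x = table.data[sid].to_numpy(dtype=float)
        rows.append({
            "sample_id": sid,
            "shannon": shannon(x, base=base),
            "simpson": simpson(x, variant=simpson_variant),
            "richness": richness(x, threshold=threshold),
        })
    return pd.DataFrame(rows).set_index("sample_id")
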