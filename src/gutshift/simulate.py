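"""Synthetic paired pre/post cohorts with planted, recoverable effects.

The generator emulates the statistical structure of a small paired
expedition cohort — ~17 subjects sampled before and after an intervention —
so every downstream stage (diversity, matched Bray-Curtis distances,
Kruskal+LDA enrichment, prevalence shifts, Spearman screens) can be
exercised and benchmarked against known ground truth:

* species intensities are log-normal (sigma ~ 2), giving the long-tailed
  rank-abundance curves typical of gut metagenomes, and samples are closed
  to 100% (taxa) or 1e6 cpm (pathways);
* per-sample richness is controlled by weighted presence sampling
  (Gumbel top-k on abundance-dependent detection weights), hitting a
  per-subject richness target drawn around the cohort mean;
* post samples are the subject's own baseline perturbed by subject-specific
  multiplicative log-normal noise — the per-subject scale is the product of
  ``shift_heterogeneity`` and a subject factor — which induces a spread of
  matched Bray-Curtis distances;
* planted effects: group-wise fold-changes (enrichment), presence/absence
  resampling to target prevalences, and feature-covariate rank coupling via
  a Gaussian copula (so the planted rho is the Spearman rho the screen
  estimates);
* whole samples can be dropped uniformly at random, emulating profiling
  rejects, after all effects are planted.

Everything is a pure function of (spec, seed): the same spec gives
bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import spearman, DegenerateCorrelation
from .profiles import (FeatureKind, ProfileTable, SampleRecord, Timepoint,
                       Units, metadata_frame)

__all__ = ["CohortSpec", "GroundTruth", "simulate_cohort", "realized_effects",
           "enrichment_benchmark", "null_two_group_benchmark", "write_cohort"]

#: Default within-subject perturbation scale.  Chosen so that a default
#: cohort's median matched Bray-Curtis distance lands in the ~0.3-0.4 range
#: reported for real paired expedition cohorts (the study this emulates
#: realized a median of 0.36).
DEFAULT_SHIFT_HETEROGENEITY = 1.0

#: Spread (log-normal sigma) of the per-subject shift factor around 1.
SUBJECT_SHIFT_SIGMA = 0.5


@dataclass
class CohortSpec:
    """Parameters of one simulated paired cohort.

    Richness targets are cohort means of detected features per sample; the
    per-subject spread mirrors the between-subject SDs of the emulated study
    (species 200 +/- 69 before, 179 +/- 53 after; pathways 76 +/- 8 and
    77 +/- 8).  Plans reference generated feature ids
    (``species_id(i)`` / ``pathway_id(i)``) and covariate names.
    """

    n_subjects: int = 17
    n_species: int = 500
    n_pathways: int = 300
    richness_target_pre: float = 200.0
    richness_target_post: float = 179.0
    richness_sd_pre: float = 69.0
    richness_sd_post: float = 53.0
    pathway_richness_pre: float = 76.0
    pathway_richness_post: float = 77.0
    pathway_richness_sd: float = 8.0
    # (feature_id, enriched group 'pre'|'post', fold change > 0)
    enrichment_plan: list[tuple[str, str, float]] = field(default_factory=list)
    # (feature_id, prevalence_pre, prevalence_post)
    prevalence_plan: list[tuple[str, float, float]] = field(default_factory=list)
    # (feature_id, covariate, target Spearman rho, timepoint)
    correlation_plan: list[tuple[str, str, float, str]] = field(default_factory=list)
    extra_covariates: list[str] = field(default_factory=list)
    shift_heterogeneity: float = DEFAULT_SHIFT_HETEROGENEITY
    subject_shift_scales: list[float] | None = None  # overrides the drawn factors
    dropout: int = 0
    seed: int = 0
    sigma_pool: float = 2.0       # log-normal spread of pool intensities
    sigma_subject: float = 1.0    # between-subject log spread per feature
    detect_slope: float = 1.0     # how strongly abundance drives detection

    def species_id(self, i: int) -> str:
        return f"Species_{i:04d}"

    def pathway_id(self, i: int) -> str:
        return f"PWY-{6000 + i}: synthetic pathway {i}"

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.richness_target_pre > self.n_species or \
                self.richness_target_post > self.n_species:
            raise ValueError("species richness target exceeds pool size")
        if self.pathway_richness_pre > self.n_pathways or \
                self.pathway_richness_post > self.n_pathways:
            raise ValueError("pathway richness target exceeds pool size")
        if self.dropout >= 2 * self.n_subjects:
            raise ValueError("dropout must leave at least one sample")
        if self.shift_heterogeneity < 0:
            raise ValueError("shift_heterogeneity must be >= 0")
        ids = ({self.species_id(i) for i in range(self.n_species)}
               | {self.pathway_id(i) for i in range(self.n_pathways)})
        for fid, group, fold in self.enrichment_plan:
            if fid not in ids:
                raise ValueError(f"enrichment_plan feature {fid!r} not in pool")
            if group not in ("pre", "post"):
                raise ValueError(f"enrichment group {group!r} not in {{pre, post}}")
            if fold <= 0:
                raise ValueError("fold change must be > 0")
        for fid, p_pre, p_post in self.prevalence_plan:
            if fid not in ids:
                raise ValueError(f"prevalence_plan feature {fid!r} not in pool")
            if not (0 <= p_pre <= 1 and 0 <= p_post <= 1):
                raise ValueError("prevalences must lie in [0, 1]")
        for fid, cov, rho, tp in self.correlation_plan:
            if fid not in ids:
                raise ValueError(f"correlation_plan feature {fid!r} not in pool")
            if abs(rho) > 1:
                raise ValueError(f"infeasible target rho {rho}")
            Timepoint(tp)
        if self.subject_shift_scales is not None \
                and len(self.subject_shift_scales) != self.n_subjects:
            raise ValueError("subject_shift_scales must have one entry per subject")


@dataclass
class GroundTruth:
    """Everything planted, for downstream recovery oracles."""
    enrichment_plan: list[tuple[str, str, float]]
    prevalence_plan: list[tuple[str, float, float]]
    correlation_plan: list[tuple[str, str, float, str]]
    subject_shift_scales: dict[str, float]
    dropped_samples: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _subject_ids(n: int) -> list[str]:
    return [f"A{i + 1:02d}" for i in range(n)]


def _gumbel_topk_mask(weights: np.ndarray, k: int, rng) -> np.ndarray:
    """Boolean mask selecting k features, weighted sampling w/o replacement."""
    keys = weights + rng.gumbel(size=len(weights))
    mask = np.zeros(len(weights), dtype=bool)
    if k > 0:
        mask[np.argpartition(-keys, k - 1)[:k]] = True
    return mask


def _richness_counts(n: int, target: float, sd: float, pool: int, rng
                     ) -> np.ndarray:
    k = np.rint(rng.normal(target, sd, size=n)).astype(int)
    return np.clip(k, 2, pool)


def _simulate_block(spec: CohortSpec, rng, n_feat: int,
                    target_pre: float, sd_pre: float,
                    target_post: float, sd_post: float,
                    subject_scales: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pre and post abundance matrices (features x subjects), open scale."""
    m = rng.normal(0.0, spec.sigma_pool, size=n_feat)           # pool intensity
    z = rng.normal(0.0, 1.0, size=(n_feat, spec.n_subjects))
    log_pre = m[:, None] + spec.sigma_subject * z

    eps = rng.normal(0.0, 1.0, size=(n_feat, spec.n_subjects))
    log_post = log_pre + subject_scales[None, :] * eps

    weights = spec.detect_slope * m
    k_pre = _richness_counts(spec.n_subjects, target_pre, sd_pre, n_feat, rng)
    same_target = (target_pre == target_post)
    k_post = (k_pre if same_target
              else _richness_counts(spec.n_subjects, target_post, sd_post,
                                    n_feat, rng))
    pre_mask = np.zeros((n_feat, spec.n_subjects), dtype=bool)
    post_mask = np.zeros((n_feat, spec.n_subjects), dtype=bool)
    for j in range(spec.n_subjects):
        pre_mask[:, j] = _gumbel_topk_mask(weights, int(k_pre[j]), rng)
        pm = pre_mask[:, j].copy()
        delta = int(k_post[j]) - int(k_pre[j])
        keys = weights + rng.gumbel(size=n_feat)
        if delta < 0:
            present = np.flatnonzero(pm)
            drop = present[np.argsort(keys[present])[:-delta]]
            pm[drop] = False
        elif delta > 0:
            absent = np.flatnonzero(~pm)
            add = absent[np.argsort(-keys[absent])[:delta]]
            pm[add] = True
        post_mask[:, j] = pm
    x_pre = np.exp(log_pre) * pre_mask
    x_post = np.exp(log_post) * post_mask
    return x_pre, x_post


def _apply_prevalence_plan(spec: CohortSpec, rng, ids: list[str],
                           x_pre: np.ndarray, x_post: np.ndarray) -> None:
    index = {fid: i for i, fid in enumerate(ids)}
    n = spec.n_subjects
    for fid, p_pre, p_post in spec.prevalence_plan:
        if fid not in index:
            continue
        i = index[fid]
        base = rng.normal(0.0, spec.sigma_pool)  # fresh intensity for imputation
        for x, p in ((x_pre, p_pre), (x_post, p_post)):
            k = int(round(p * n))
            chosen = rng.choice(n, size=k, replace=False)
            present = np.zeros(n, dtype=bool)
            present[chosen] = True
            vals = x[i].copy()
            need = present & (vals == 0)
            vals[need] = np.exp(base + spec.sigma_subject
                                * rng.normal(size=int(need.sum())))
            vals[~present] = 0.0
            x[i] = vals


def _apply_enrichment_plan(spec: CohortSpec, ids: list[str],
                           x_pre: np.ndarray, x_post: np.ndarray) -> None:
    index = {fid: i for i, fid in enumerate(ids)}
    for fid, group, fold in spec.enrichment_plan:
        if fid not in index:
            continue
        i = index[fid]
        if group == "post":
            x_post[i] *= fold
        else:
            x_pre[i] *= fold


def _closure(x: np.ndarray, total: float) -> np.ndarray:
    sums = x.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("a simulated sample has zero total abundance")
    return x * (total / sums)


def _copula_covariate(feature_vals: np.ndarray, rho_s: float, rng,
                      loc: float = 100.0, scale: float = 15.0) -> np.ndarray:
    """Covariate rank-coupled to a feature at target Spearman rho."""
    n = len(feature_vals)
    ranks = stats.rankdata(feature_vals)
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))  # Blom normal scores
    z = (z - z.mean()) / (z.std() or 1.0)
    rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Spearman -> Gaussian copula
    eps = rng.normal(size=n)
    v = rho_g * z + np.sqrt(max(0.0, 1.0 - rho_g ** 2)) * eps
    return loc + scale * v


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[ProfileTable, ProfileTable, list[SampleRecord],
                               GroundTruth]:
    """Generate (taxon table, pathway table, metadata, ground truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_ids(spec.n_subjects)
    pre_ids = [f"{s}_pre" for s in subjects]
    post_ids = [f"{s}_post" for s in subjects]

    if spec.subject_shift_scales is not None:
        factors = np.asarray(spec.subject_shift_scales, dtype=float)
    else:
        factors = rng.lognormal(0.0, SUBJECT_SHIFT_SIGMA, size=spec.n_subjects)
    scales = spec.shift_heterogeneity * factors

    sp_ids = [spec.species_id(i) for i in range(spec.n_species)]
    pw_ids = [spec.pathway_id(i) for i in range(spec.n_pathways)]

    sp_pre, sp_post = _simulate_block(
        spec, rng, spec.n_species, spec.richness_target_pre, spec.richness_sd_pre,
        spec.richness_target_post, spec.richness_sd_post, scales)
    pw_pre, pw_post = _simulate_block(
        spec, rng, spec.n_pathways, spec.pathway_richness_pre,
        spec.pathway_richness_sd, spec.pathway_richness_post,
        spec.pathway_richness_sd, scales)

    _apply_prevalence_plan(spec, rng, sp_ids, sp_pre, sp_post)
    _apply_prevalence_plan(spec, rng, pw_ids, pw_pre, pw_post)
    _apply_enrichment_plan(spec, sp_ids, sp_pre, sp_post)
    _apply_enrichment_plan(spec, pw_ids, pw_pre, pw_post)

    taxa = ProfileTable(
        pd.DataFrame(np.hstack([_closure(sp_pre, 100.0), _closure(sp_post, 100.0)]),
                     index=sp_ids, columns=pre_ids + post_ids),
        kind=FeatureKind.TAXON, level="species", units=Units.RELATIVE_PERCENT)
    paths = ProfileTable(
        pd.DataFrame(np.hstack([_closure(pw_pre, 1e6), _closure(pw_post, 1e6)]),
                     index=pw_ids, columns=pre_ids + post_ids),
        kind=FeatureKind.PATHWAY, units=Units.CPM)

    # covariates: planted couplings first (in plan order), then nulls
    cov_values: dict[tuple[str, str], np.ndarray] = {}
    planted_names = []
    for fid, cov, rho, tp in spec.correlation_plan:
        table = taxa if fid in set(sp_ids) else paths
        cols = pre_ids if tp == "pre" else post_ids
        vals = table.data.loc[fid, cols].to_numpy(dtype=float)
        cov_values[(cov, tp)] = _copula_covariate(vals, rho, rng)
        planted_names.append(cov)
    all_covs = list(dict.fromkeys(planted_names + list(spec.extra_covariates)))
    for cov in all_covs:
        for tp in ("pre", "post"):
            if (cov, tp) not in cov_values:
                cov_values[(cov, tp)] = 100.0 + 15.0 * rng.normal(size=spec.n_subjects)

    metadata: list[SampleRecord] = []
    for j, subj in enumerate(subjects):
        for tp, sid in (("pre", pre_ids[j]), ("post", post_ids[j])):
            cov = {c: float(cov_values[(c, tp)][j]) for c in all_covs}
            metadata.append(SampleRecord(sid, subj, Timepoint(tp), cov))

    dropped: list[str] = []
    if spec.dropout:
        all_ids = pre_ids + post_ids
        dropped = sorted(rng.choice(all_ids, size=spec.dropout, replace=False))
        keep = [s for s in all_ids if s not in set(dropped)]
        taxa = taxa.subset_samples(keep)
        paths = paths.subset_samples(keep)
        metadata = [r for r in metadata if r.sample_id not in set(dropped)]

    truth = GroundTruth(
        enrichment_plan=list(spec.enrichment_plan),
        prevalence_plan=list(spec.prevalence_plan),
        correlation_plan=list(spec.correlation_plan),
        subject_shift_scales={s: float(v) for s, v in zip(subjects, scales)},
        dropped_samples=dropped,
    )
    return taxa, paths, metadata, truth


# ---------------------------------------------------------------------------
# realized-effect oracle
# ---------------------------------------------------------------------------

def realized_effects(taxa: ProfileTable, paths: ProfileTable,
                     metadata: list[SampleRecord], truth: GroundTruth
                     ) -> pd.DataFrame:
    """Recompute what each planted effect actually looks like in the cohort.

    The downstream recovery tests compare their discoveries against these
    realized values, not the nominal plan (small-n sampling noise and
    closure shift them).
    """
    sp = set(taxa.feature_ids)
    pre = [r.sample_id for r in metadata if r.timepoint == Timepoint.PRE]
    post = [r.sample_id for r in metadata if r.timepoint == Timepoint.POST]
    rows = []

    def values(fid, cols):
        table = taxa if fid in sp else paths
        return table.renormalize().data.loc[fid, cols].to_numpy(dtype=float)

    for fid, group, fold in truth.enrichment_plan:
        num_cols, den_cols = (post, pre) if group == "post" else (pre, post)
        num, den = values(fid, num_cols).mean(), values(fid, den_cols).mean()
        realized = float(num / den) if den > 0 else float("inf")
        rows.append({"effect": "enrichment", "feature_id": fid,
                     "detail": group, "planned": fold, "realized": realized})
    for fid, p_pre, p_post in truth.prevalence_plan:
        rows.append({"effect": "prevalence_pre", "feature_id": fid, "detail": "pre",
                     "planned": p_pre,
                     "realized": float((values(fid, pre) > 0).mean())})
        rows.append({"effect": "prevalence_post", "feature_id": fid, "detail": "post",
                     "planned": p_post,
                     "realized": float((values(fid, post) > 0).mean())})
    for fid, cov, rho, tp in truth.correlation_plan:
        recs = [r for r in metadata if r.timepoint == Timepoint(tp)]
        x = values(fid, [r.sample_id for r in recs])
        y = np.array([r.covariates.get(cov, np.nan) for r in recs])
        try:
            realized, _ = spearman(x, y)
        except (DegenerateCorrelation, ValueError):
            realized = float("nan")
        rows.append({"effect": "correlation", "feature_id": fid,
                     "detail": f"{cov}@{tp}", "planned": rho,
                     "realized": realized})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standard benchmarks
# ---------------------------------------------------------------------------

def enrichment_benchmark(seed: int, n_features: int = 300, n_planted: int = 5,
                         fold: float = 4.0, n_per_group: int = 10
                         ) -> tuple[ProfileTable, list[str], list[str]]:
    """The standard planted-enrichment benchmark.

    A paired cohort of ``n_per_group`` subjects at low within-pair noise,
    with ``n_planted`` species enriched ``fold``-fold in the post group;
    planted features are drawn from the upper-middle abundance range so the
    effect is expressed above the detection floor.  Returns
    (species table, pre/post group labels per sample, planted feature ids).
    """
    base = dict(
        n_subjects=n_per_group, n_species=n_features, n_pathways=10,
        richness_target_pre=int(n_features * 0.8),
        richness_target_post=int(n_features * 0.8),
        richness_sd_pre=0.0, richness_sd_post=0.0,
        pathway_richness_pre=8, pathway_richness_post=8, pathway_richness_sd=0.0,
        shift_heterogeneity=0.15, sigma_subject=0.5, dropout=0, seed=seed)
    # probe run (no plan consumes no extra rng draws): rank features by
    # realized abundance and plant in the upper-middle range
    probe_taxa, _, _, _ = simulate_cohort(CohortSpec(**base))
    order = np.argsort(-probe_taxa.values.mean(axis=1))
    candidates = order[10:n_features // 2]
    rng = np.random.default_rng(seed + 1)
    planted_idx = rng.choice(candidates, size=n_planted, replace=False)
    planted = [probe_taxa.feature_ids[int(i)] for i in sorted(planted_idx)]
    spec = CohortSpec(**base,
                      enrichment_plan=[(f, "post", fold) for f in planted])
    taxa, _, metadata, _ = simulate_cohort(spec)
    labels = []
    meta = {r.sample_id: r for r in metadata}
    for sid in taxa.sample_ids:
        labels.append(meta[sid].timepoint.value)
    return taxa, labels, planted

def correlation_benchmark(seed: int, n_features: int = 200, rho: float = 0.95,
                          n_subjects: int = 17, timepoint: str = "pre",
                          covariate: str = "covariate_1"
                          ) -> tuple[ProfileTable, list[SampleRecord], str]:
    """Standard planted-correlation benchmark: one coupled pair among nulls.

    The coupling is planted on a feature detected in every sample at the
    screened timepoint (zeros would tie the ranks and cap the attainable
    Spearman rho below the target).  Returns (species table, metadata,
    planted feature id); the planted covariate is ``covariate``.
    """
    base = dict(
        n_subjects=n_subjects, n_species=n_features, n_pathways=10,
        richness_target_pre=int(n_features * 0.8),
        richness_target_post=int(n_features * 0.8),
        richness_sd_pre=0.0, richness_sd_post=0.0,
        pathway_richness_pre=8, pathway_richness_post=8, pathway_richness_sd=0.0,
        seed=seed)
    probe_taxa, _, probe_meta, _ = simulate_cohort(CohortSpec(**base))
    cols = [r.sample_id for r in probe_meta if r.timepoint == Timepoint(timepoint)]
    sub = probe_taxa.data[cols]
    detected = np.flatnonzero((sub.to_numpy() > 0).all(axis=1))
    order = np.argsort(-sub.to_numpy().mean(axis=1))
    ranked = [i for i in order if i in set(detected)]
    rng = np.random.default_rng(seed + 1)
    lo = min(5, len(ranked) - 1)
    hi = max(lo + 1, min(50, len(ranked)))
    planted_i = int(ranked[int(rng.integers(lo, hi))])
    planted = probe_taxa.feature_ids[planted_i]
    spec = CohortSpec(**base,
                      correlation_plan=[(planted, covariate, rho, timepoint)])
    taxa, _, metadata, _ = simulate_cohort(spec)
    return taxa, metadata, planted


def null_two_group_benchmark(seed: int, n_features: int = 300,
                             n_per_group: int = 10
                             ) -> tuple[ProfileTable, list[str]]:
    """Null benchmark: two independent groups with no planted effects.

    Baseline samples of 2*``n_per_group`` subjects, split into two groups at
    random — the differential-enrichment gate should fire at its nominal
    alpha rate.
    """
    rng = np.random.default_rng(seed)
    spec = CohortSpec(
        n_subjects=2 * n_per_group, n_species=n_features, n_pathways=10,
        richness_target_pre=int(n_features * 0.8),
        richness_target_post=int(n_features * 0.8),
        richness_sd_pre=0.0, richness_sd_post=0.0,
        pathway_richness_pre=8, pathway_richness_post=8, pathway_richness_sd=0.0,
        shift_heterogeneity=0.0, sigma_subject=0.5, dropout=0, seed=seed)
    taxa, _, metadata, _ = simulate_cohort(spec)
    pre_ids = [r.sample_id for r in metadata if r.timepoint == Timepoint.PRE]
    table = taxa.subset_samples(pre_ids)
    perm = rng.permutation(len(pre_ids))
    labels = ["g1" if i in set(perm[:n_per_group]) else "g2"
              for i in range(len(pre_ids))]
    return table, labels


# ---------------------------------------------------------------------------
# writers (MetaPhlAn / HUMAnN dialects for the CLI)
# ---------------------------------------------------------------------------

def write_cohort(out_dir, taxa: ProfileTable, paths: ProfileTable,
                 metadata: list[SampleRecord], truth: GroundTruth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lineage = [f"k__Bacteria|s__{fid}" for fid in taxa.feature_ids]
    with open(out / "taxa_metaphlan.tsv", "w") as fh:
        fh.write("#mpa_synthetic_cohort\n")
        fh.write("clade_name\t" + "\t".join(taxa.sample_ids) + "\n")
        for lin, row in zip(lineage, taxa.values):
            fh.write(lin + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    with open(out / "pathways_humann.tsv", "w") as fh:
        fh.write("# Pathway\t" + "\t".join(paths.sample_ids) + "\n")
        for fid, row in zip(paths.feature_ids, paths.values):
            fh.write(fid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    metadata_frame(metadata).to_csv(out / "metadata.tsv", sep="\t",
                                    float_format="%.10g")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
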