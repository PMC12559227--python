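"""End-to-end orchestration: cohort directory in, report bundle out.

``run_all`` executes the full paired analysis — align, alpha diversity,
Bray-Curtis / matched distances / PERMANOVA, pre-vs-post enrichment, paired
signed-rank follow-up, prevalence shifts, responder stratification with
baseline contrasts and baseline enrichment, and the configured correlation
screens — writing one subdirectory of TSVs per stage plus a machine-readable
``summary.json`` that enumerates every parameter used.

All randomness is drawn from one seeded generator per stage, the stage seed
derived from the master seed by hashing the stage name, so each stage is
reproducible independently of execution order.  Runs with the same config
and seed produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta, correlation, diversity, enrichment, prevalence, responders
from .profiles import (ProfileTable, SampleRecord, Timepoint, align,
                       read_functional_profile, read_metadata,
                       read_taxonomic_profile)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ScreenSpec", "run_all", "load_config",
           "PipelineStageError"]

_FLOAT_FMT = "%.10g"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class ScreenSpec:
    """One correlation screen: data block x covariates x timepoint x subset."""
    block: str = "species"          # species | pathways
    covariates: str = "all"         # "all" or '+'-joined covariate names
    timepoint: str = "pre"          # pre | post
    subjects: str = "all"           # all | large_shift | small_shift

    @classmethod
    def parse(cls, text: str) -> "ScreenSpec":
        parts = [p.strip() for p in text.split(":")]
        if len(parts) != 4:
            raise ValueError(f"screen spec {text!r} is not "
                             "block:covariates:timepoint:subjects")
        return cls(*parts)

    def tag(self) -> str:
        return f"{self.block}_{self.timepoint}_{self.subjects}"


@dataclass
class PipelineConfig:
    taxon_table: str
    pathway_table: str
    metadata: str
    level: str = "species"
    alpha: float = 0.05
    lda_threshold: float = 2.0
    permanova_permutations: int = 999
    prevalence_threshold: float = 0.0
    prevalence_top_k: int = 20
    responder_threshold: float | None = None
    screens: list[ScreenSpec] = field(default_factory=lambda: [
        ScreenSpec("species", "all", "pre", "large_shift"),
        ScreenSpec("species", "all", "post", "large_shift"),
        ScreenSpec("pathways", "all", "pre", "large_shift"),
        ScreenSpec("pathways", "all", "post", "large_shift"),
    ])
    seed: int = 0

    def validate(self) -> None:
        for name in ("taxon_table", "pathway_table", "metadata"):
            path = Path(getattr(self, name))
            if not path.is_file():
                raise FileNotFoundError(f"{name} file not found: {path}")


def load_config(path) -> PipelineConfig:
    """Load a flat key/value config file (YAML mapping of scalars).

    ``screens`` may be a comma-separated list of
    ``block:covariates:timepoint:subjects`` strings.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    if "screens" in raw and isinstance(raw["screens"], str):
        raw["screens"] = [ScreenSpec.parse(s)
                          for s in raw["screens"].split(",") if s.strip()]
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def stage_seed(master: int, stage: str) -> int:
    digest = hashlib.blake2s(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _enrichment_frame(results) -> pd.DataFrame:
    df = _records_frame(results)
    return df[["feature_id", "enriched_group", "kruskal_p", "lda_score",
               "significant"]]


def _mean_sd(values) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n": int(len(arr))}


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run the full paired-cohort analysis and write the report bundle."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": _config_dict(config)}

    # ---- load & align ----------------------------------------------------
    stage = "load"
    try:
        taxa = read_taxonomic_profile(config.taxon_table, level=config.level)
        paths = read_functional_profile(config.pathway_table)
        metadata = read_metadata(config.metadata)
        taxa, meta_taxa, report_taxa = align(taxa, metadata)
        paths, metadata, report_paths = align(paths, meta_taxa)
        taxa, metadata, _ = align(taxa, metadata)
        summary["alignment"] = {
            "n_samples": taxa.n_samples,
            "n_species": taxa.n_features,
            "n_pathways": paths.n_features,
            "unpaired_subjects": report_paths.unpaired_subjects,
            "dropped_from_metadata": report_taxa.dropped_from_metadata,
        }
    except Exception as e:  # noqa: BLE001 - stage context added
        raise PipelineStageError(stage, str(e)) from e

    pre_ids = [r.sample_id for r in metadata if r.timepoint == Timepoint.PRE]
    post_ids = [r.sample_id for r in metadata if r.timepoint == Timepoint.POST]
    tp_by_sample = {r.sample_id: r.timepoint.value for r in metadata}

    # ---- alpha diversity -------------------------------------------------
    stage = "diversity"
    try:
        alpha_sp = diversity.alpha_diversity_table(taxa)
        alpha_pw = diversity.alpha_diversity_table(paths)
        _write_tsv(alpha_sp, out / "diversity" / "alpha_species.tsv", index=True)
        _write_tsv(alpha_pw, out / "diversity" / "alpha_pathways.tsv", index=True)
        summary["diversity"] = {
            "species_richness_pre": _mean_sd(alpha_sp.loc[pre_ids, "richness"]),
            "species_richness_post": _mean_sd(alpha_sp.loc[post_ids, "richness"]),
            "pathway_richness_pre": _mean_sd(alpha_pw.loc[pre_ids, "richness"]),
            "pathway_richness_post": _mean_sd(alpha_pw.loc[post_ids, "richness"]),
            "shannon_pre": _mean_sd(alpha_sp.loc[pre_ids, "shannon"]),
            "shannon_post": _mean_sd(alpha_sp.loc[post_ids, "shannon"]),
        }
    except Exception as e:
        raise PipelineStageError(stage, str(e)) from e

    # ---- beta diversity --------------------------------------------------
    stage = "beta"
    try:
        dm = beta.distance_matrix(taxa)
        _write_tsv(dm.to_frame(), out / "beta" / "distance_species.tsv", index=True)
        matched, skipped = beta.matched_distances(dm, metadata)
        _write_tsv(_records_frame(matched), out / "beta" / "matched_distances.tsv")
        perm = beta.permanova(dm, [tp_by_sample[s] for s in dm.sample_ids],
                              n_permutations=config.permanova_permutations,
                              seed=stage_seed(config.seed, "permanova"))
        (out / "beta" / "permanova.json").write_text(
            json.dumps(perm.__dict__, indent=2, sort_keys=True) + "\n")
        med = float(np.median([m.distance for m in matched]))
        summary["beta"] = {
            "median_matched_distance": med,
            "matched_subjects": len(matched),
            "skipped_subjects": skipped,
            "permanova_pre_vs_post": perm.__dict__,
        }
    except Exception as e:
        raise PipelineStageError(stage, str(e)) from e

    # ---- pre-vs-post enrichment + paired follow-up -----------------------
    stage = "enrichment"
    try:
        labels = [tp_by_sample[s] for s in taxa.sample_ids]
        summary["enrichment"] = {}
        flagged: list[tuple[str, str]] = []
        for name, table in (("species", taxa), ("pathways", paths)):
            tbl_labels = [tp_by_sample[s] for s in table.sample_ids]
            res = enrichment.lefse(table, tbl_labels, alpha=config.alpha,
                                   lda_threshold=config.lda_threshold,
                                   positive_group="post")
            _write_tsv(_enrichment_frame(res),
                       out / "enrichment" / f"lefse_{name}.tsv")
            sig = [r for r in res if r.significant]
            summary["enrichment"][name] = {
                "n_significant": len(sig),
                "enriched_post": [r.feature_id for r in sig
                                  if r.enriched_group == "post"],
                "enriched_pre": [r.feature_id for r in sig
                                 if r.enriched_group == "pre"],
            }
            flagged.extend((name, r.feature_id) for r in sig)
        wil_rows = []
        for name, fid in flagged:
            table = taxa if name == "species" else paths
            w = enrichment.paired_wilcoxon(table, metadata, fid)
            wil_rows.append({"block": name, **w.__dict__})
        wil_df = pd.DataFrame(wil_rows, columns=["block", "feature_id", "n_pairs",
                                                 "statistic", "p_value",
                                                 "direction", "degenerate"])
        _write_tsv(wil_df, out / "enrichment" / "paired_wilcoxon.tsv")
        summary["enrichment"]["paired_wilcoxon_significant"] = [
            r["feature_id"] for r in wil_rows if r["p_value"] < config.alpha]
    except Exception as e:
        raise PipelineStageError(stage, str(e)) from e

    # ---- prevalence ------------------------------------------------------
    stage = "prevalence"
    try:
        summary["prevalence"] = {}
        for name, table in (("species", taxa), ("pathways", paths)):
            recs = prevalence.prevalence_table(table, metadata,
                                               threshold=config.prevalence_threshold)
            _write_tsv(prevalence.prevalence_frame(recs),
                       out / "prevalence" / f"{name}.tsv", index=True)
            top = prevalence.top_prevalence_shifts(recs, config.prevalence_top_k)
            _write_tsv(prevalence.prevalence_frame(top),
                       out / "prevalence" / f"top_shifts_{name}.tsv", index=True)
            summary["prevalence"][name] = {
                "max_abs_delta": max(abs(r.delta) for r in recs),
                "top_shift_features": [r.feature_id for r in top[:5]],
            }
    except Exception as e:
        raise PipelineStageError(stage, str(e)) from e

    # ---- responder stratification ---------------------------------------
    stage = "responders"
    try:
        labels = responders.classify_responders(matched,
                                                threshold=config.responder_threshold)
        _write_tsv(_records_frame(labels), out / "responders" / "labels.tsv")
        groups = {l.subject_id: l.group for l in labels}
        large = [s for s, g in groups.items() if g == responders.LARGE]
        small = [s for s, g in groups.items() if g == responders.SMALL]
        summary["responders"] = {
            "threshold_used": labels[0].threshold_used,
            "large_shift": sorted(large),
            "small_shift": sorted(small),
        }

        # baseline richness + covariate contrasts, one BH family
        rich_pre = {r.subject_id: alpha_sp.loc[r.sample_id, "richness"]
                    for r in metadata if r.timepoint == Timepoint.PRE}
        variables: dict[str, tuple[list, list]] = {
            "baseline_species_richness": (
                [rich_pre[s] for s in large if s in rich_pre],
                [rich_pre[s] for s in small if s in rich_pre]),
        }
        cov_names = sorted({c for r in metadata for c in r.covariates})
        for cov in cov_names:
            vals = {r.subject_id: r.covariates[cov] for r in metadata
                    if r.timepoint == Timepoint.PRE}
            variables[cov] = ([vals.get(s, np.nan) for s in large],
                              [vals.get(s, np.nan) for s in small])
        contrasts = responders.contrast_family(variables, alpha=config.alpha)
        cdf = _records_frame(contrasts)
        cdf["group_mean_large"] = [c.group_means[0] for c in contrasts]
        cdf["group_mean_small"] = [c.group_means[1] for c in contrasts]
        cdf = cdf.drop(columns=["group_means"])
        _write_tsv(cdf, out / "responders" / "baseline_contrasts.tsv")
        summary["responders"]["baseline_contrasts_raw_significant"] = [
            c.variable for c in contrasts if c.significant_raw]
        summary["responders"]["baseline_contrasts_adjusted_significant"] = [
            c.variable for c in contrasts if c.significant_adjusted]

        summary["responders"]["baseline_enrichment"] = {}
        for name, table in (("species", taxa), ("pathways", paths)):
            res = responders.baseline_enrichment(
                table, metadata, labels, alpha=config.alpha,
                lda_threshold=config.lda_threshold)
            _write_tsv(_enrichment_frame(res),
                       out / "responders" / f"baseline_lefse_{name}.tsv")
            summary["responders"]["baseline_enrichment"][name] = [
                {"feature_id": r.feature_id, "enriched_group": r.enriched_group}
                for r in res if r.significant]
    except Exception as e:
        raise PipelineStageError(stage, str(e)) from e

    # ---- correlation screens ---------------------------------------------
    stage = "correlations"
    try:
        cov_names = sorted({c for r in metadata for c in r.covariates})
        summary["correlations"] = {}
        for sspec in config.screens:
            table = taxa if sspec.block == "species" else paths
            covs = cov_names if sspec.covariates == "all" \
                else sspec.covariates.split("+")
            if not covs:
                summary["correlations"][sspec.tag()] = {
                    "bh_family_size": 0, "significant": [],
                    "note": "no covariates in metadata"}
                continue
            subjects = None
            if sspec.subjects == "large_shift":
                subjects = large
            elif sspec.subjects == "small_shift":
                subjects = small
            res = correlation.screen(table, metadata, covs, sspec.timepoint,
                                     subjects=subjects, alpha=config.alpha)
            df = correlation.correlation_frame(res)
            tag = sspec.tag()
            path = out / "correlations" / f"screen_{tag}.tsv"
            path.parent.mkdir(parents=True, exist_ok=True)
            family = int(np.isfinite(df["p_raw"]).sum()) if len(df) else 0
            with open(path, "w") as fh:
                fh.write(f"# BH family size: {family}\n")
                df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
            summary["correlations"][tag] = {
                "bh_family_size": family,
                "significant": [
                    {"feature_id": r.feature_id, "covariate": r.covariate,
                     "rho": round(r.rho, 4), "q_bh": float(r.q_bh)}
                    for r in res if r.significant],
            }
    except Exception as e:
        raise PipelineStageError(stage, str(e)) from e

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n")
    return summary


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["screens"] = [f"{s['block']}:{s['covariates']}:{s['timepoint']}:{s['subjects']}"
                    for s in d["screens"]]
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
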