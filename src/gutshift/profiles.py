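"""Profile tables, sample metadata, and the table dialects they are read from.

The pipeline consumes the outputs of shotgun-metagenomics profilers:

* taxonomic relative-abundance tables in the MetaPhlAn merged-table dialect
  (tab-separated, first column a pipe-delimited clade lineage such as
  ``k__Bacteria|p__Firmicutes|...|s__Blautia_luti``, values in percent);
* functional pathway-abundance tables in the HUMAnN ``pathabundance`` dialect
  (feature ids like ``PWY-6703: preQ0 biosynthesis``, optional taxon-stratified
  rows marked by a ``|`` after the pathway id);
* a plain sample-metadata TSV carrying subject id, timepoint (pre/post) and
  continuous covariates (dietary intakes, blood markers, performance indices).

Everything downstream operates on :class:`ProfileTable` (features x samples,
non-negative, absence encoded as 0) and lists of :class:`SampleRecord`.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
    "strain": "t__",
}

#: Per-sample column-sum slack (fraction of the nominal total) tolerated in a
#: percent table before renormalization triggers a warning.  MetaPhlAn rounds
#: to a handful of decimals, so sums of 99.99-100.01 are routine.
PERCENT_SUM_TOLERANCE = 0.01


class FeatureKind(str, enum.Enum):
    TAXON = "taxon"
    PATHWAY = "pathway"


class Units(str, enum.Enum):
    RELATIVE_PERCENT = "relative_percent"
    RELATIVE_FRACTION = "relative_fraction"
    CPM = "cpm"
    ARBITRARY = "arbitrary"


class ProfileError(ValueError):
    """Malformed or inconsistent profile input."""


@dataclass
class ProfileTable:
    """A features x samples abundance matrix with its provenance.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative matrix, index = feature ids, columns = sample ids.
        Absent features are 0, never NaN.
    kind : FeatureKind
        ``taxon`` or ``pathway``.
    level : str, optional
        Taxonomic rank for single-rank taxon tables (e.g. ``"species"``).
    units : Units
        Scale of the values (percent, fraction, counts-per-million, arbitrary).
    """

    data: pd.DataFrame
    kind: FeatureKind = FeatureKind.TAXON
    level: str | None = None
    units: Units = Units.ARBITRARY

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        self.units = Units(self.units)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ProfileError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ProfileError(f"duplicate sample id: {dup!r}")
        if self.data.isna().any().any():
            raise ProfileError("profile table contains missing cells; absence must be 0")
        if (self.data.values < 0).any():
            raise ProfileError("profile table contains negative abundances")

    # -- convenience views ------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ProfileTable":
        return ProfileTable(self.data.copy(), self.kind, self.level, self.units)

    def subset_samples(self, sample_ids: list[str]) -> "ProfileTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ProfileError(f"samples not in table: {missing}")
        return ProfileTable(self.data.loc[:, sample_ids], self.kind, self.level, self.units)

    def renormalize(self, total: float | None = None) -> "ProfileTable":
        """Rescale every sample column to sum to ``total``.

        Default totals: 100 for percent tables, 1e6 for cpm, 1 for fraction.
        Idempotent.  Raises on all-zero columns (a sample with no signal
        cannot be renormalized).
        """
        if total is None:
            total = {
                Units.RELATIVE_PERCENT: 100.0,
                Units.CPM: 1e6,
                Units.RELATIVE_FRACTION: 1.0,
                Units.ARBITRARY: 1.0,
            }[self.units]
        sums = self.data.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise ProfileError(f"sample {zero.index[0]!r} has zero total abundance")
        return ProfileTable(self.data * (total / sums), self.kind, self.level, self.units)


class Timepoint(str, enum.Enum):
    PRE = "pre"
    POST = "post"


@dataclass
class SampleRecord:
    """One sample: identity, timepoint, and continuous covariates.

    Covariate values are real numbers; a missing measurement is ``NaN``
    (missingness is a metadata concept only — profile tables encode
    absence as 0).
    """

    sample_id: str
    subject_id: str
    timepoint: Timepoint
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoint = Timepoint(self.timepoint)


class MetadataError(ValueError):
    """Malformed or inconsistent sample metadata."""


def metadata_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Long/wide view of metadata records: one row per sample."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "subject_id": r.subject_id,
               "timepoint": r.timepoint.value}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def sample_map(records: list[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_raw_tsv(path) -> pd.DataFrame:
    """Read a TSV with no parsing: every cell a string, no comment handling
    (dialect headers may legitimately start with '#')."""
    with open(path, "r", encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ProfileError(f"{path}: empty table")
    width = max(len(r) for r in rows)
    rows = [r + [None] * (width - len(r)) for r in rows]
    return pd.DataFrame(rows)


def _looks_like_taxid_column(col: pd.Series) -> bool:
    # NCBI-taxid companion column: every cell is integers optionally
    # pipe-joined (e.g. "2|1239|186801"), or empty.
    def ok(cell: str) -> bool:
        if cell == "" or cell is None:
            return True
        return all(part.isdigit() for part in str(cell).split("|") if part != "")
    return bool(col.map(ok).all())


def read_taxonomic_profile(path, level: str = "species") -> ProfileTable:
    """Read a MetaPhlAn merged-abundance table at a single taxonomic rank.

    Keeps only rows whose *terminal* rank equals ``level``, strips the lineage
    down to the final name (without the rank prefix), and renormalizes every
    sample column to 100.  A column whose sum deviates from 100 by more than
    1% triggers a logged warning before renormalization.

    Both ``#clade_name`` and ``clade_name`` header dialects are accepted, and
    an optional all-integer NCBI-taxid second column is ignored.
    """
    if level not in RANK_PREFIXES:
        raise ProfileError(f"unknown taxonomic rank {level!r}")
    prefix = RANK_PREFIXES[level]

    raw = _read_raw_tsv(path)
    # Locate the header row: first row whose first cell names the clade column
    # (possibly '#'-prefixed); other '#' lines above it are comments.
    header_idx = None
    for i in range(len(raw)):
        first = str(raw.iat[i, 0])
        if first.lstrip("#").strip() in ("clade_name", "ID", "taxonomy"):
            header_idx = i
            break
        if not first.startswith("#"):
            break
    if header_idx is not None:
        header = [str(c) for c in raw.iloc[header_idx]]
        body = raw.iloc[header_idx + 1:].reset_index(drop=True)
    else:
        # headerless (already comment-stripped) dialect is rejected: sample
        # ids are required
        raise ProfileError(f"{path}: no header row with sample ids found")
    body = body[~body[0].astype(str).str.startswith("#")].reset_index(drop=True)
    if body.empty:
        raise ProfileError(f"{path}: no data rows")

    sample_cols = list(range(1, body.shape[1]))
    # optional NCBI taxid column directly after the lineage
    if len(sample_cols) >= 2 and _looks_like_taxid_column(body[1]):
        sample_cols = sample_cols[1:]
    sample_ids = [header[c].strip() for c in sample_cols]

    mask = body[0].map(lambda s: _terminal_rank_prefix(str(s)) == prefix)
    body = body[mask]
    if body.empty:
        raise ProfileError(f"{path}: no rows at rank {level!r}")

    feature_ids = [str(s).split("|")[-1][len(prefix):] for s in body[0]]
    values = np.empty((len(body), len(sample_cols)), dtype=float)
    for j, c in enumerate(sample_cols):
        for i, cell in enumerate(body[c]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ProfileError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None

    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    table = ProfileTable(df, kind=FeatureKind.TAXON, level=level,
                         units=Units.RELATIVE_PERCENT)
    sums = df.sum(axis=0)
    off = sums[(sums - 100.0).abs() > 100.0 * PERCENT_SUM_TOLERANCE]
    for sid, s in off.items():
        logger.warning("sample %s: %s-level abundances sum to %.4g; "
                       "renormalizing to 100", sid, level, s)
    return table.renormalize(100.0)


def _terminal_rank_prefix(lineage: str) -> str | None:
    last = lineage.split("|")[-1]
    return last[:3] if len(last) >= 3 and last[1:3] == "__" else None


def read_functional_profile(path, drop_stratified: bool = True) -> ProfileTable:
    """Read a HUMAnN pathabundance table into a cpm-scaled pathway table.

    Stratified rows (a ``|`` after the pathway id, e.g.
    ``PWY-6703: preQ0 biosynthesis|g__Escherichia.s__Escherichia_coli``) are
    dropped by default, keeping only community-level rows.  Columns are
    total-sum scaled to 1e6 (counts per million).
    """
    df = _read_raw_tsv(path)
    header = [str(c) for c in df.iloc[0]]
    if not header[0].lstrip("#").strip().lower().startswith(("pathway", "id")):
        raise ProfileError(f"{path}: first column header {header[0]!r} does not "
                           "look like a HUMAnN pathway column")
    body = df.iloc[1:].reset_index(drop=True)
    body = body[~body[0].astype(str).str.startswith("#")].reset_index(drop=True)
    if body.empty:
        raise ProfileError(f"{path}: no data rows")
    sample_ids = [h.strip() for h in header[1:]]

    if drop_stratified:
        body = body[~body[0].astype(str).str.contains(r"\|", regex=True)]
        body = body.reset_index(drop=True)
    if body.empty:
        raise ProfileError(f"{path}: no community-level rows")

    feature_ids = [str(s) for s in body[0]]
    seen: set[str] = set()
    for fid in feature_ids:
        if fid in seen:
            raise ProfileError(f"{path}: duplicate pathway id {fid!r}")
        seen.add(fid)

    values = np.empty((len(body), len(sample_ids)), dtype=float)
    for j in range(len(sample_ids)):
        for i, cell in enumerate(body[j + 1]):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ProfileError(
                    f"{path}: non-numeric cell {cell!r} at pathway "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if v < 0:
                raise ProfileError(f"{path}: negative abundance {v} at pathway "
                                   f"{feature_ids[i]!r}, sample {sample_ids[j]!r}")
            values[i, j] = v

    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    table = ProfileTable(df, kind=FeatureKind.PATHWAY, units=Units.CPM)
    return table.renormalize(1e6)


RESERVED_METADATA_COLUMNS = ("sample_id", "subject_id", "timepoint")


def read_metadata(path) -> list[SampleRecord]:
    """Read the sample-metadata TSV.

    Required columns: ``sample_id``, ``subject_id``, ``timepoint`` (pre/post).
    Every other column is parsed as a real-valued covariate; blank cells are
    recorded as missing (NaN), never as 0.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in RESERVED_METADATA_COLUMNS:
        if col not in df.columns:
            raise MetadataError(f"{path}: missing required column {col!r}")
    records: list[SampleRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    seen_samples: set[str] = set()
    covariate_cols = [c for c in df.columns if c not in RESERVED_METADATA_COLUMNS]
    for _, row in df.iterrows():
        tp = str(row["timepoint"]).strip()
        if tp not in (Timepoint.PRE.value, Timepoint.POST.value):
            raise MetadataError(f"{path}: timepoint {tp!r} not in {{pre, post}}")
        sid, subj = str(row["sample_id"]).strip(), str(row["subject_id"]).strip()
        if sid in seen_samples:
            raise MetadataError(f"{path}: duplicated sample_id {sid!r}")
        pair = (subj, tp)
        if pair in seen_pairs:
            raise MetadataError(f"{path}: duplicated (subject, timepoint) {pair}")
        seen_samples.add(sid)
        seen_pairs.add(pair)
        cov: dict[str, float] = {}
        for c in covariate_cols:
            cell = row[c]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) \
                    or str(cell).strip() == "":
                cov[c] = float("nan")
            else:
                try:
                    cov[c] = float(cell)
                except ValueError:
                    raise MetadataError(
                        f"{path}: non-numeric covariate {c!r} = {cell!r} "
                        f"for sample {sid!r}") from None
        records.append(SampleRecord(sid, subj, Timepoint(tp), cov))
    if not records:
        raise MetadataError(f"{path}: no metadata rows")
    return records


@dataclass
class AlignmentReport:
    """What `align` kept and what it had to discard."""
    kept_samples: list[str]
    dropped_from_table: list[str]
    dropped_from_metadata: list[str]
    unpaired_subjects: list[str]


def align(table: ProfileTable, metadata: list[SampleRecord]
          ) -> tuple[ProfileTable, list[SampleRecord], AlignmentReport]:
    """Intersect table and metadata sample ids and report incomplete pairs.

    Sample order follows the metadata (pre-timepoint first within subject
    ordering as given).  Subjects left without both timepoints after the
    intersection — e.g. because profiling rejected a sample — are listed in
    the report, not dropped: downstream stages decide what needs pairs.
    """
    meta_ids = [r.sample_id for r in metadata]
    table_ids = set(table.sample_ids)
    kept = [s for s in meta_ids if s in table_ids]
    if not kept:
        raise ProfileError("no samples shared between table and metadata")
    kept_set = set(kept)
    records = [r for r in metadata if r.sample_id in kept_set]

    by_subject: dict[str, set[str]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, set()).add(r.timepoint.value)
    unpaired = sorted(s for s, tps in by_subject.items() if len(tps) < 2)

    report = AlignmentReport(
        kept_samples=kept,
        dropped_from_table=[s for s in table.sample_ids if s not in kept_set],
        dropped_from_metadata=[s for s in meta_ids if s not in kept_set],
        unpaired_subjects=unpaired,
    )
    if report.unpaired_subjects:
        logger.info("align: subjects without complete pre/post pairs: %s",
                    ", ".join(report.unpaired_subjects))
    return table.subset_samples(kept), records, report


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_long_tsv(table: ProfileTable, path) -> None:
    """Canonical long-format writer: feature_id, sample_id, value."""
    long = (table.data.rename_axis("feature_id")
            .reset_index()
            .melt(id_vars="feature_id", var_name="sample_id", value_name="value"))
    long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_wide_tsv(table: ProfileTable, path, id_column: str = "feature_id") -> None:
    out = table.data.rename_axis(id_column)
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_long_tsv(path, kind: FeatureKind = FeatureKind.TAXON,
                  units: Units = Units.ARBITRARY, level: str | None = None
                  ) -> ProfileTable:
    long = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "sample_id": str})
    wide = long.pivot(index="feature_id", columns="sample_id", values="value")
    wide = wide.loc[pd.unique(long["feature_id"]), pd.unique(long["sample_id"])]
    wide.index.name = None
    wide.columns.name = None
    return ProfileTable(wide.fillna(0.0), kind=kind, units=units, level=level)


def write_metadata_tsv(records: list[SampleRecord], path) -> None:
    metadata_frame(records).to_csv(path, sep="\t", float_format="%.10g")
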