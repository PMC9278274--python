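"""Data model and tabular I/O for amplicon feature-table studies.

The central object is a :class:`FeatureTable`: an integer count matrix of
sequence features (ASVs, or taxa after aggregation) by samples.  Samples are
described by a :class:`Metadata` collection (environment class, season, farm
linkage, control flag) and features optionally by a :class:`TaxonomyTable`
(seven-rank lineage).  All tables read and write plain delimited text (TSV or
CSV), the common export format of amplicon pipelines; the internal orientation
is always features in rows.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ENVIRONMENTS",
    "SEASONS",
    "RANKS",
    "HOME_ENVIRONMENT",
    "STABLE_ENVIRONMENT",
    "ValidationError",
    "FeatureTable",
    "SampleRecord",
    "Metadata",
    "TaxonomyTable",
    "StudyBundle",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "join_metadata",
    "derive_seed",
]

#: Recognised sample environment classes.
ENVIRONMENTS = (
    "cow_home",
    "pig_home",
    "suburban_home",
    "cow_stable",
    "pig_stable",
    "negative_control",
)

#: Sampling seasons. "unknown" is used when the field was not recorded.
SEASONS = ("summer", "winter", "unknown")

#: Taxonomic ranks, most to least inclusive.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Home environment per livestock type (for matched home-stable analyses).
HOME_ENVIRONMENT = {"cow": "cow_home", "pig": "pig_home"}
#: Stable environment per livestock type.
STABLE_ENVIRONMENT = {"cow": "cow_stable", "pig": "pig_stable"}

_DELIMITERS = {".tsv": "\t", ".csv": ",", ".txt": "\t", ".tab": "\t"}


class ValidationError(ValueError):
    """Raised when a table, metadata collection, or cross-reference is invalid."""


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a stable child seed (< 2**31) from a master seed and string tokens.

    Hash-based so that results never depend on the order in which seeded
    stages or samples are processed.
    """
    h = hashlib.blake2b(digest_size=4)
    h.update(str(int(seed)).encode())
    for tok in tokens:
        h.update(b"\x00" + str(tok).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Integer count matrix, features x samples, with aligned identifier lists.

    Invariants (enforced on construction): non-negative integer entries,
    dimensions matching the identifier lists, and no duplicate identifiers.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integers")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {name} identifiers: {dup}")
        self.counts = counts

    # -- basic properties ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def feature_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    # -- selection ----------------------------------------------------------

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(
            self.counts[:, idx], list(self.feature_ids), [self.sample_ids[i] for i in idx]
        )

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return FeatureTable(
            self.counts[idx, :], [self.feature_ids[i] for i in idx], list(self.sample_ids)
        )

    def drop_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        drop = set(feature_ids)
        keep = [f for f in self.feature_ids if f not in drop]
        return self.select_features(keep)

    def relative_abundance(self) -> np.ndarray:
        """Closure: per-sample proportions (features x samples). All-zero samples error."""
        sums = self.sample_sums()
        if np.any(sums == 0):
            bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise ValidationError(f"all-zero samples: {bad}")
        return self.counts / sums[np.newaxis, :]

    # -- frames -------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return _DELIMITERS.get(path.suffix.lower(), "\t")


def read_feature_table(
    path: str | Path,
    orientation: str = "features_in_rows",
    delimiter: str | None = None,
) -> FeatureTable:
    """Read a delimited count table with one header row and one label column.

    ``orientation`` says what the *file* rows are; the returned table is
    always features x samples.  Delimiter is inferred from the extension
    (.tsv -> tab, .csv -> comma) unless given explicitly.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    text = path.read_text(encoding="utf-8")
    header = text.splitlines()[0].split(sep)[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path.name}: duplicate column labels: {dup}")
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and the like
        raise ValidationError(f"{path.name}: malformed table: {exc}") from exc
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path.name}: duplicate row labels: {dup}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValidationError(f"{path.name}: non-numeric cell: {exc}") from exc
    if np.any(np.isnan(values)):
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path.name}: missing cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if np.any(values != np.floor(values)):
        i, j = np.argwhere(values != np.floor(values))[0]
        raise ValidationError(
            f"{path.name}: non-integer cell {values[i, j]} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path.name}: negative cell {values[i, j]} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    df = pd.DataFrame(values.astype(np.int64), index=df.index, columns=df.columns)
    if orientation == "samples_in_rows":
        df = df.T
    return FeatureTable.from_dataframe(df)


def write_feature_table(
    table: FeatureTable, path: str | Path, delimiter: str | None = None
) -> None:
    """Write features-in-rows delimited text (UTF-8, Unix newlines)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = table.to_dataframe()
    df.index.name = "feature_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep=sep, lineterminator="\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata: environment class, season, farm linkage, control flag."""

    sample_id: str
    environment: str
    season: str = "unknown"
    farm_id: str | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown environment {self.environment!r}"
            )
        if self.season not in SEASONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown season {self.season!r}"
            )
        if self.is_control != (self.environment == "negative_control"):
            raise ValidationError(
                f"sample {self.sample_id!r}: is_control must be true exactly for "
                f"negative_control samples (got environment={self.environment!r}, "
                f"is_control={self.is_control})"
            )


class Metadata:
    """An ordered collection of :class:`SampleRecord` with lookup helpers."""

    def __init__(self, records: Iterable[SampleRecord]):
        self.records: list[SampleRecord] = list(records)
        self._index: dict[str, SampleRecord] = {}
        for rec in self.records:
            if rec.sample_id in self._index:
                raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
            self._index[rec.sample_id] = rec
        # A farm linkage id may appear at most twice within one environment
        # class (e.g. one summer and one winter visit); more indicates a
        # mis-keyed linkage column.
        per_farm_env: dict[tuple[str, str], int] = {}
        for rec in self.records:
            if rec.farm_id:
                key = (rec.farm_id, rec.environment)
                per_farm_env[key] = per_farm_env.get(key, 0) + 1
        bad = sorted(k for k, v in per_farm_env.items() if v > 2)
        if bad:
            raise ValidationError(
                f"farm_id shared by more than 2 samples of one environment class: {bad}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._index[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def subset(self, sample_ids: Sequence[str]) -> "Metadata":
        return Metadata(self._index[s] for s in sample_ids)

    def environment_of(self, sample_id: str) -> str:
        return self._index[sample_id].environment

    def group_ids(self, environment: str) -> list[str]:
        if environment not in ENVIRONMENTS:
            raise ValidationError(f"unknown environment {environment!r}")
        return [r.sample_id for r in self.records if r.environment == environment]

    def group_sizes(self) -> dict[str, int]:
        sizes = {env: 0 for env in ENVIRONMENTS}
        for r in self.records:
            sizes[r.environment] += 1
        return {env: n for env, n in sizes.items() if n > 0}

    def control_ids(self) -> list[str]:
        return [r.sample_id for r in self.records if r.is_control]

    def true_sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records if not r.is_control]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "environment": [r.environment for r in self.records],
                "season": [r.season for r in self.records],
                "farm_id": [r.farm_id if r.farm_id is not None else "" for r in self.records],
                "is_control": [r.is_control for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Metadata":
        required = {"sample_id", "environment"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing required columns: {sorted(missing)}")
        records = []
        for _, row in df.iterrows():
            farm = row.get("farm_id", "")
            farm = None if farm in ("", None) or pd.isna(farm) else str(farm)
            season = row.get("season", "unknown")
            season = "unknown" if season in ("", None) or pd.isna(season) else str(season)
            is_control = row.get("is_control", row["environment"] == "negative_control")
            if isinstance(is_control, str):
                is_control = is_control.strip().lower() in ("true", "1", "yes")
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    environment=str(row["environment"]),
                    season=season,
                    farm_id=farm,
                    is_control=bool(is_control),
                )
            )
        return cls(records)


def read_metadata(path: str | Path, delimiter: str | None = None) -> Metadata:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return Metadata.from_dataframe(df)


def write_metadata(meta: Metadata, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        meta.to_dataframe().to_csv(fh, sep=sep, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


class TaxonomyTable:
    """feature_id -> seven-rank lineage; missing ranks are empty strings.

    A lineage must be prefix-complete: once a rank is missing every finer
    rank is missing too (no gaps).
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self.lineages: dict[str, tuple[str, ...]] = {}
        for fid, ranks in lineages.items():
            ranks = tuple(str(r) if r is not None else "" for r in ranks)
            if len(ranks) != len(RANKS):
                raise ValidationError(
                    f"feature {fid!r}: expected {len(RANKS)} ranks, got {len(ranks)}"
                )
            seen_gap = False
            for r in ranks:
                if r == "":
                    seen_gap = True
                elif seen_gap:
                    raise ValidationError(
                        f"feature {fid!r}: lineage has a gap (named rank below a missing one)"
                    )
            self.lineages[str(fid)] = ranks

    def __len__(self) -> int:
        return len(self.lineages)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages

    def label_at(self, feature_id: str, level: str) -> str:
        """Taxon label of a feature at a rank; unnamed ranks render as
        "Unclassified <nearest named parent>" (or "Unclassified")."""
        if level not in RANKS:
            raise ValueError(f"unknown rank {level!r}")
        depth = RANKS.index(level)
        lineage = self.lineages.get(feature_id)
        if lineage is None:
            return "Unclassified"
        if lineage[depth]:
            return lineage[depth]
        parent = next((lineage[d] for d in range(depth - 1, -1, -1) if lineage[d]), "")
        return f"Unclassified {parent}".strip()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            {fid: list(ranks) for fid, ranks in self.lineages.items()},
            orient="index",
            columns=list(RANKS),
        )
        df.index.name = "feature_id"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TaxonomyTable":
        missing = set(RANKS) - set(df.columns)
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {sorted(missing)}")
        if "feature_id" in df.columns:
            df = df.set_index("feature_id")
        return cls({str(fid): [row[r] for r in RANKS] for fid, row in df.iterrows()})


def read_taxonomy(path: str | Path, delimiter: str | None = None) -> TaxonomyTable:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return TaxonomyTable.from_dataframe(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        tax.to_dataframe().to_csv(fh, sep=sep, lineterminator="\n")


# ---------------------------------------------------------------------------
# Study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """A feature table joined with validated metadata (and optional taxonomy)."""

    table: FeatureTable
    metadata: Metadata
    taxonomy: TaxonomyTable | None = None
    #: sample ids present in metadata but not in the table (reported, dropped)
    extra_metadata_ids: list[str] = field(default_factory=list)

    def group_sizes(self) -> dict[str, int]:
        return self.metadata.group_sizes()

    def subset_samples(self, sample_ids: Sequence[str]) -> "StudyBundle":
        return StudyBundle(
            self.table.select_samples(sample_ids),
            self.metadata.subset(sample_ids),
            self.taxonomy,
        )


def join_metadata(
    table: FeatureTable, meta: Metadata, taxonomy: TaxonomyTable | None = None
) -> StudyBundle:
    """Join a table with metadata into a validated bundle.

    Every table sample must have metadata (error listing offenders);
    metadata-only samples are dropped and recorded on the bundle.
    """
    missing = [s for s in table.sample_ids if s not in meta]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    extra = [s for s in meta.sample_ids if s not in set(table.sample_ids)]
    sub = meta.subset(table.sample_ids)
    return StudyBundle(table, sub, taxonomy, extra_metadata_ids=extra)
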