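"""Reading, writing and aligning omic feature tables and cohort metadata.

Feature tables are tab-separated matrices of samples x features; counts for
the sequencing-based layers (metagenomic species, metatranscriptomic
pathways, viromic viruses) and ion intensities for metabolomics.  Metadata
is one row per sample with the participant identifier, diagnosis and the
demographic covariates used as fixed effects downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DuplicateIDError,
    MetadataConsistencyError,
    MetadataParseError,
    NonNumericValueError,
)

logger = logging.getLogger(__name__)


class Layer(str, Enum):
    """The four omic layers."""

    MGN = "MGN"  # metagenomics: species-level taxonomic counts
    MTS = "MTS"  # metatranscriptomics: pathway-level counts
    VRM = "VRM"  # viromics: virus counts
    MBL = "MBL"  # metabolomics: compound ion intensities


#: Transform states a table can be in.
RAW, CLR, LOG10 = "raw", "clr", "log10"

DIAGNOSES = ("nonIBD", "CD", "UC")
_DIAGNOSIS_LOOKUP = {d.lower(): d for d in DIAGNOSES}
_SEXES = ("female", "male")

METADATA_COLUMNS = (
    "sample_id",
    "participant_id",
    "diagnosis",
    "age",
    "sex",
    "race",
    "antibiotic_use",
    "site",
    "week",
)


@dataclass
class OmicLayerTable:
    """One omic layer: a dense samples x features matrix plus provenance.

    ``data`` is indexed by sample id with feature ids as columns.  The
    ``transform`` flag records whether values are raw counts/intensities or
    have been CLR- or log10-transformed.
    """

    layer: Layer
    data: pd.DataFrame
    transform: str = RAW

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        if self.data.index.has_duplicates:
            raise DuplicateIDError(f"duplicate sample ids in {self.layer.value} table")
        if self.data.columns.has_duplicates:
            raise DuplicateIDError(f"duplicate feature ids in {self.layer.value} table")
        values = self.data.to_numpy()
        if values.size == 0:
            return
        if not np.issubdtype(values.dtype, np.number):
            raise NonNumericValueError(
                f"{self.layer.value} table contains non-numeric values"
            )
        if not np.all(np.isfinite(values)):
            raise NonNumericValueError(
                f"{self.layer.value} table contains non-finite values"
            )
        if self.transform == RAW and (values < 0).any():
            raise NonNumericValueError(
                f"raw {self.layer.value} values must be non-negative"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, transform: str | None = None) -> "OmicLayerTable":
        return OmicLayerTable(self.layer, data, transform or self.transform)

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicLayerTable":
        return self.with_data(self.data.loc[:, list(feature_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicLayerTable":
        return self.with_data(self.data.loc[list(sample_ids)])


@dataclass
class CohortMetadata:
    """Per-sample cohort metadata with participant-level diagnosis.

    Diagnosis is three-level (nonIBD / CD / UC); the binary response used in
    modeling is IBD = 1 for CD or UC, 0 for nonIBD.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise MetadataParseError(f"metadata missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise DuplicateIDError("duplicate sample ids in metadata")
        bad_dx = set(df["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise MetadataParseError(f"unknown diagnosis levels: {sorted(bad_dx)}")
        per_part = df.groupby("participant_id")["diagnosis"].nunique()
        inconsistent = per_part[per_part > 1]
        if len(inconsistent):
            raise MetadataConsistencyError(
                "participants with multiple diagnoses: "
                f"{sorted(inconsistent.index.tolist())}"
            )
        bad_sex = set(df["sex"]) - set(_SEXES)
        if bad_sex:
            raise MetadataParseError(f"unknown sex levels: {sorted(bad_sex)}")
        if (df["age"] <= 0).any():
            raise MetadataParseError("age must be > 0")
        if (df["week"] < 0).any():
            raise MetadataParseError("week must be >= 0")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def participants(self) -> list[str]:
        return sorted(self.data["participant_id"].unique())

    def participant_diagnosis(self) -> pd.Series:
        return self.data.groupby("participant_id")["diagnosis"].first()

    def ibd_labels(self) -> pd.Series:
        """Binary response per sample: 1 for CD or UC, 0 for nonIBD."""
        return (self.data["diagnosis"] != "nonIBD").astype(int).set_axis(
            self.data["sample_id"]
        )

    def participant_labels(self) -> pd.Series:
        """Binary response per participant."""
        dx = self.participant_diagnosis()
        return (dx != "nonIBD").astype(int)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CohortMetadata":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return CohortMetadata(keep.copy())

    def subset_participants(self, participant_ids: Iterable[str]) -> "CohortMetadata":
        keep = self.data[self.data["participant_id"].isin(set(participant_ids))]
        return CohortMetadata(keep.copy())


def read_feature_table(
    path: str | Path,
    layer: Layer | str,
    orientation: str = "samples",
) -> OmicLayerTable:
    """Read a tab-separated feature table.

    ``orientation`` declares what the rows are: ``"samples"`` (default) or
    ``"features"`` (the table is transposed on read).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    if orientation not in ("samples", "features"):
        raise ValueError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DuplicateIDError(f"duplicate identifiers in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise NonNumericValueError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "features":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicLayerTable(Layer(layer), df, RAW)


def write_feature_table(table: OmicLayerTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.data.copy()
    out.index.name = "sample_id"
    # repr-precision floats so a write/read round trip is value-identical
    out.to_csv(path, sep="\t", float_format=None)


_TRUE = {"true", "yes", "1", "t", "y"}
_FALSE = {"false", "no", "0", "f", "n"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise MetadataParseError(f"cannot parse boolean value {value!r}")


def read_metadata(path: str | Path) -> CohortMetadata:
    """Read and validate a tab-separated metadata file.

    Required columns: sample_id, participant_id, diagnosis, age, sex, race,
    antibiotic_use, site, week.  Diagnosis and sex are case-folded to the
    canonical levels; missing race maps to the explicit level "unknown".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataParseError(f"metadata missing columns: {missing}")
    df = df.copy()
    dx = df["diagnosis"].str.strip().str.lower()
    unknown = set(dx) - set(_DIAGNOSIS_LOOKUP)
    if unknown:
        raise MetadataParseError(f"unknown diagnosis levels: {sorted(unknown)}")
    df["diagnosis"] = dx.map(_DIAGNOSIS_LOOKUP)
    df["sex"] = df["sex"].str.strip().str.lower()
    df["race"] = df["race"].fillna("unknown").replace("", "unknown")
    df["antibiotic_use"] = df["antibiotic_use"].map(_parse_bool)
    try:
        df["age"] = df["age"].astype(float)
        df["week"] = df["week"].astype(float).astype(int)
    except ValueError as exc:
        raise MetadataParseError(f"non-numeric age/week: {exc}") from exc
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.data.to_csv(path, sep="\t", index=False)


def align(table: OmicLayerTable, meta: CohortMetadata) -> OmicLayerTable:
    """Restrict a table to samples present in both table and metadata.

    Samples are returned in metadata order; dropped ids are logged.
    """
    meta_ids = meta.sample_ids
    table_ids = set(table.sample_ids)
    shared = [s for s in meta_ids if s in table_ids]
    if not shared:
        raise AlignmentError(
            f"no shared samples between {table.layer.value} table and metadata"
        )
    dropped = sorted(table_ids - set(shared))
    if dropped:
        logger.info(
            "align(%s): dropped %d samples absent from metadata: %s",
            table.layer.value,
            len(dropped),
            dropped[:10],
        )
    return table.with_data(table.data.loc[shared])
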