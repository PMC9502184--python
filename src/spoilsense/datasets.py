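"""Shared data model and CSV I/O for the spoilage-prediction pipeline.

All tabular artifacts are UTF-8 CSV with a header row, ``.`` decimal
separator and ``sample_id`` as the first column.  Spectral matrices store
one wavenumber per column, labelled with the numeric wavenumber (up to two
decimals); feature tables store named feature columns.  Sample metadata
lives in a separate CSV keyed by ``sample_id`` and alignment is always by
id, never by row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "SpectralDataset",
    "FeatureTable",
    "SplitPlan",
    "load_spectral_dataset",
    "write_spectral_dataset",
    "load_feature_table",
    "write_feature_table",
    "write_metadata",
    "validate_dataset",
]

ORIGINS = ("MI", "SAMS")

METADATA_COLUMNS = ("sample_id", "origin", "harvest_year", "storage_temp", "storage_day", "tvc")


@dataclass(frozen=True)
class SampleRecord:
    """One physical seaweed sample.

    ``tvc`` is the measured total viable count in log10 CFU/g; it may be
    ``None`` for prediction-only samples.
    """

    sample_id: str
    origin: str
    harvest_year: int
    storage_temp: float
    storage_day: float
    tvc: float | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(
                f"origin must be one of {ORIGINS}, got {self.origin!r} for sample {self.sample_id!r}"
            )
        if self.storage_day < 0:
            raise ValueError(f"storage_day must be >= 0 for sample {self.sample_id!r}")


def _check_records(values: np.ndarray, records: Sequence[SampleRecord]) -> None:
    if values.ndim != 2:
        raise ValueError("values must be a 2-D matrix")
    if values.shape[0] != len(records):
        raise ValueError(
            f"matrix has {values.shape[0]} rows but {len(records)} sample records"
        )


@dataclass
class SpectralDataset:
    """Wavenumber grid plus sample x wavenumber absorbance matrix.

    The grid may be stored in acquisition (descending) order; all
    operations index by wavenumber value, not position.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    records: list[SampleRecord]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        _check_records(self.absorbance, self.records)
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError("column count does not match wavenumber grid size")
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def tvc(self) -> np.ndarray:
        """Response vector; raises if any sample lacks a measured TVC."""
        missing = [r.sample_id for r in self.records if r.tvc is None]
        if missing:
            raise ValueError(f"samples without tvc: {missing}")
        return np.array([r.tvc for r in self.records], dtype=float)

    def subset(self, sample_ids: Iterable[str]) -> "SpectralDataset":
        wanted = list(sample_ids)
        index = {r.sample_id: i for i, r in enumerate(self.records)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in wanted]
        return SpectralDataset(
            self.wavenumbers.copy(),
            self.absorbance[rows].copy(),
            [self.records[i] for i in rows],
        )


@dataclass
class FeatureTable:
    """Named-feature matrix (MSI bands, e-nose sensors, or selected wavenumbers)."""

    feature_names: list[str]
    values: np.ndarray
    records: list[SampleRecord]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_records(self.values, self.records)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature name count")
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = sorted({n for n in self.feature_names if self.feature_names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def tvc(self) -> np.ndarray:
        missing = [r.sample_id for r in self.records if r.tvc is None]
        if missing:
            raise ValueError(f"samples without tvc: {missing}")
        return np.array([r.tvc for r in self.records], dtype=float)

    def subset(self, sample_ids: Iterable[str]) -> "FeatureTable":
        wanted = list(sample_ids)
        index = {r.sample_id: i for i, r in enumerate(self.records)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in wanted]
        return FeatureTable(
            list(self.feature_names),
            self.values[rows].copy(),
            [self.records[i] for i in rows],
        )


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test sample-id sets produced by a splitting scheme."""

    train_ids: frozenset
    test_ids: frozenset
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise ValueError("train and test sets overlap")
        if not self.train_ids or not self.test_ids:
            raise ValueError("train and test sets must both be non-empty")


# ---------------------------------------------------------------------------
# CSV I/O


def _format_wavenumber(w: float) -> str:
    s = f"{float(w):.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _read_metadata(metadata_path: str | Path) -> dict[str, SampleRecord]:
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns and c != "tvc"]
    if missing_cols:
        raise ValueError(f"metadata file missing columns: {missing_cols}")
    records: dict[str, SampleRecord] = {}
    for _, row in meta.iterrows():
        sid = str(row["sample_id"])
        if sid in records:
            raise ValueError(f"duplicate sample_id in metadata: {sid!r}")
        tvc = None
        if "tvc" in meta.columns and not pd.isna(row["tvc"]):
            tvc = float(row["tvc"])
        records[sid] = SampleRecord(
            sample_id=sid,
            origin=str(row["origin"]),
            harvest_year=int(row["harvest_year"]),
            storage_temp=float(row["storage_temp"]),
            storage_day=float(row["storage_day"]),
            tvc=tvc,
        )
    return records


def _read_wide_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected sample_id column plus at least one data column")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    ids = [str(s) for s in df.iloc[:, 0]]
    columns = [str(c) for c in df.columns[1:]]
    block = df.iloc[:, 1:]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~block.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at sample {ids[r]!r}, column {columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at sample {ids[r]!r}, column {columns[c]!r}")
    return ids, columns, numeric.to_numpy(dtype=float)


def _align(ids: list[str], meta: dict[str, SampleRecord]) -> list[SampleRecord]:
    missing = [s for s in ids if s not in meta]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    return [meta[s] for s in ids]


def load_spectral_dataset(path: str | Path, metadata_path: str | Path) -> SpectralDataset:
    """Load a wide spectral CSV plus its metadata table, aligned by sample_id."""
    ids, columns, values = _read_wide_matrix(path)
    try:
        wavenumbers = np.array([float(c) for c in columns])
    except ValueError as exc:
        raise ValueError(f"{path}: header must carry numeric wavenumbers ({exc})") from None
    records = _align(ids, _read_metadata(metadata_path))
    return SpectralDataset(wavenumbers, values, records)


def load_feature_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Load a named-feature CSV plus its metadata table, aligned by sample_id."""
    ids, columns, values = _read_wide_matrix(path)
    records = _align(ids, _read_metadata(metadata_path))
    return FeatureTable(columns, values, records)


def _write_wide(path: str | Path, ids: list[str], columns: list[str], values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(np.asarray(values)))[0]
        raise ValueError(
            f"refusing to write non-finite value at sample {ids[r]!r}, column {columns[c]!r}"
        )
    df = pd.DataFrame(values, columns=columns)
    df.insert(0, "sample_id", ids)
    df.to_csv(path, index=False)


def write_spectral_dataset(ds: SpectralDataset, path: str | Path) -> None:
    columns = [_format_wavenumber(w) for w in ds.wavenumbers]
    _write_wide(path, ds.sample_ids, columns, ds.absorbance)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    _write_wide(path, table.sample_ids, list(table.feature_names), table.values)


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "origin": [r.origin for r in records],
            "harvest_year": [r.harvest_year for r in records],
            "storage_temp": [r.storage_temp for r in records],
            "storage_day": [r.storage_day for r in records],
            "tvc": [r.tvc if r.tvc is not None else "" for r in records],
        }
    )
    df.to_csv(path, index=False)


def validate_dataset(dataset: SpectralDataset | FeatureTable) -> list[str]:
    """Report invariant violations; empty list iff the dataset is clean.

    Never raises: every problem becomes one human-readable issue string
    naming the violated invariant and the offending sample ids.
    """
    issues: list[str] = []
    ids = dataset.sample_ids
    seen: set[str] = set()
    dupes = sorted({s for s in ids if s in seen or seen.add(s)})  # type: ignore[func-returns-value]
    if dupes:
        issues.append(f"duplicate sample_id: {dupes}")
    for r in dataset.records:
        if r.tvc is not None and not (math.isfinite(r.tvc) and r.tvc >= 0):
            issues.append(f"tvc must be finite and >= 0: sample {r.sample_id!r} has {r.tvc}")
    values = dataset.absorbance if isinstance(dataset, SpectralDataset) else dataset.values
    if not np.all(np.isfinite(values)):
        rows = sorted({ids[r] for r in np.argwhere(~np.isfinite(values))[:, 0]})
        issues.append(f"non-finite values in rows: {rows}")
    if isinstance(dataset, SpectralDataset) and dataset.wavenumbers.size > 1:
        d = np.diff(dataset.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            issues.append("wavenumber grid not strictly monotone")
    return issues
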