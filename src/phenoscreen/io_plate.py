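"""Plate-aware I/O for high-content screening feature tables.

The central container is :class:`FeatureTable`: a pandas DataFrame of
numeric morphological features with per-well metadata (plate, well,
compound, dose, cell line, well role) carried in dedicated columns.
Feature tables arrive as CellProfiler-style CSV exports where metadata
columns are distinguished from feature columns by a configurable name
prefix (``Metadata_`` by default).

All screens follow the 384-well convention: rows A–P, columns 01–24,
optionally imaged at up to 6 fields of view per well.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Conventions shared across the package
# ---------------------------------------------------------------------------

#: Metadata columns of a feature table, in canonical order.
METADATA_COLUMNS = ["plate", "well", "field", "cell_line", "compound", "dose_nM", "role"]

#: Well roles recognised in plate maps.
ROLES = ("sample", "dmso", "positive")

#: Default prefix marking metadata columns in CellProfiler-style exports.
METADATA_PREFIX = "Metadata_"

#: Processing stages a table moves through, in contract order.
STAGES = ("raw", "aggregated", "filtered", "normalized", "transformed", "scaled")

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class PlateFormatError(ValueError):
    """Raised on malformed plate maps, well addresses, or feature tables."""


class PipelineStateError(RuntimeError):
    """Raised when processing stages are applied out of contract order."""


def parse_well(well: str) -> tuple[str, int]:
    """Parse a 384-well address like ``"A01"`` (or ``"A1"``) into (row, column).

    Raises :class:`PlateFormatError` for addresses outside rows A–P or
    columns 1–24.
    """
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise PlateFormatError(f"invalid well address {well!r}")
    row = m.group(1).upper()
    col = int(m.group(2))
    if not (1 <= col <= 24):
        raise PlateFormatError(f"invalid well address {well!r}: column {col} outside 1-24")
    return row, col


def format_well(row: str, col: int) -> str:
    """Format (row, column) as a zero-padded address, e.g. ``("A", 1)`` -> ``"A01"``."""
    return f"{row.upper()}{col:02d}"


def normalize_well(well: str) -> str:
    """Normalise a well address to zero-padded form (``"A1"`` -> ``"A01"``)."""
    return format_well(*parse_well(well))


@dataclass(frozen=True)
class WellAddress:
    """A plate/well (optionally field) location on a 384-well plate."""

    plate_id: str
    well: str
    field: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "well", normalize_well(self.well))
        if self.field is not None and not (1 <= int(self.field) <= 6):
            raise PlateFormatError(f"field {self.field} outside 1..6")


@dataclass(frozen=True)
class WellMetadata:
    """Treatment annotation for one well."""

    address: WellAddress
    cell_line: str
    compound_id: str | None
    dose_nM: float | None
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise PlateFormatError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role == "dmso" and self.compound_id is not None:
            raise PlateFormatError("dmso wells must not carry a compound_id")
        if self.dose_nM is not None and not self.dose_nM > 0:
            raise PlateFormatError(f"dose_nM must be positive, got {self.dose_nM}")


@dataclass
class FeatureTable:
    """Wells (or fields) x numeric features, with screening metadata.

    ``data`` holds the metadata columns (a subset of
    :data:`METADATA_COLUMNS`) followed by the numeric feature columns
    named in ``feature_names``. ``level`` is ``"field"`` or ``"well"``;
    ``stage`` tracks progress through the preprocessing contract.
    """

    data: pd.DataFrame
    feature_names: list[str]
    level: str = "well"
    stage: str = "raw"

    def __post_init__(self):
        if self.level not in ("field", "well"):
            raise ValueError(f"level must be 'field' or 'well', got {self.level!r}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise PlateFormatError("duplicate feature names")
        missing = [c for c in self.feature_names if c not in self.data.columns]
        if missing:
            raise PlateFormatError(f"feature columns absent from data: {missing[:5]}")
        feats = self.data[self.feature_names]
        all_missing = [c for c in self.feature_names if feats[c].isna().all()]
        if all_missing:
            raise PlateFormatError(f"all-missing feature columns: {all_missing[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        """The numeric feature block, in ``feature_names`` order."""
        return self.data[self.feature_names]

    @property
    def matrix(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def metadata(self) -> pd.DataFrame:
        cols = [c for c in METADATA_COLUMNS if c in self.data.columns]
        return self.data[cols]

    def with_features(self, values: np.ndarray, feature_names: list[str] | None = None,
                      stage: str | None = None) -> "FeatureTable":
        """Return a copy with the feature block replaced."""
        names = self.feature_names if feature_names is None else list(feature_names)
        out = pd.concat([self.metadata.reset_index(drop=True),
                         pd.DataFrame(np.asarray(values, dtype=float), columns=names)],
                        axis=1)
        return FeatureTable(out, names, level=self.level,
                            stage=self.stage if stage is None else stage)

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise PipelineStateError(
                f"operation requires stage in {allowed}, table is at {self.stage!r}"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_plate_map(path: str | Path) -> list[WellMetadata]:
    """Read a plate map CSV (columns plate, well, cell_line, compound, dose_nM, role).

    Role strings are normalised case-insensitively. Duplicate plate x well
    pairs and unknown roles are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise PlateFormatError(f"no wells in plate map {path}")
    required = ["plate", "well", "cell_line", "compound", "dose_nM", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateFormatError(f"plate map missing column(s): {', '.join(missing)}")

    df = df.copy()
    df["well"] = df["well"].map(normalize_well)
    dup = df.duplicated(subset=["plate", "well"], keep=False)
    if dup.any():
        pairs = sorted(set(map(tuple, df.loc[dup, ["plate", "well"]].to_numpy())))
        raise PlateFormatError(f"duplicate plate x well pairs: {pairs[:10]}")

    records: list[WellMetadata] = []
    for row in df.itertuples(index=False):
        role = str(row.role).strip().lower()
        compound = None if pd.isna(row.compound) or str(row.compound).strip() == "" else str(row.compound)
        if role == "dmso":
            compound = None
        dose = None if pd.isna(row.dose_nM) or str(row.dose_nM).strip() == "" else float(row.dose_nM)
        records.append(WellMetadata(
            address=WellAddress(plate_id=str(row.plate), well=str(row.well)),
            cell_line=str(row.cell_line),
            compound_id=compound,
            dose_nM=dose,
            role=role,
        ))
    return records


def read_feature_table(path: str | Path, plate_map: str | Path | list[WellMetadata] | None = None,
                       metadata_prefix: str = METADATA_PREFIX,
                       level: str | None = None) -> FeatureTable:
    """Read a feature table CSV (or Parquet) into a :class:`FeatureTable`.

    Metadata columns are identified by ``metadata_prefix`` (CellProfiler
    convention) or by bare canonical names; everything else is coerced to a
    numeric feature. An optional plate map supplies per-well annotation
    joined on (plate, well).
    """
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise PlateFormatError(f"empty feature table {path}")

    rename = {}
    for col in df.columns:
        if col.startswith(metadata_prefix):
            rename[col] = col[len(metadata_prefix):].lower()
    df = df.rename(columns=rename)

    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    for mandatory in ("plate", "well"):
        if mandatory not in meta_cols:
            raise PlateFormatError(f"feature table missing mandatory metadata column {mandatory!r}")
    feature_names = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not feature_names:
        raise PlateFormatError("feature table contains no feature columns")

    df = df.copy()
    df["well"] = df["well"].map(normalize_well)
    for col in feature_names:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise PlateFormatError(
                f"non-numeric feature value {df[col].iloc[i]!r} at row {i}, column {col!r}"
            )
        df[col] = coerced

    if plate_map is not None:
        records = plate_map if isinstance(plate_map, list) else read_plate_map(plate_map)
        ann = pd.DataFrame([{
            "plate": r.address.plate_id, "well": r.address.well,
            "cell_line": r.cell_line, "compound": r.compound_id,
            "dose_nM": r.dose_nM, "role": r.role,
        } for r in records])
        overlap = [c for c in ("cell_line", "compound", "dose_nM", "role") if c in df.columns]
        df = df.drop(columns=overlap).merge(ann, on=["plate", "well"], how="left", validate="many_to_one")

    if level is None:
        level = "field" if "field" in df.columns else "well"
    ordered = [c for c in METADATA_COLUMNS if c in df.columns] + feature_names
    return FeatureTable(df[ordered].reset_index(drop=True), feature_names, level=level)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame | FeatureTable, path: str | Path,
                metadata_prefix: str = "") -> None:
    """Write a result table (or FeatureTable) as UTF-8 CSV at full float precision.

    Column order is deterministic: metadata columns in canonical order first,
    then feature/result columns in their existing order.
    """
    if isinstance(table, FeatureTable):
        df = table.data
        ordered = [c for c in METADATA_COLUMNS if c in df.columns] + table.feature_names
        df = df[ordered]
        if metadata_prefix:
            df = df.rename(columns={c: metadata_prefix + c for c in METADATA_COLUMNS
                                    if c in df.columns})
    else:
        df = table
    if len(df) == 0:
        raise PlateFormatError("refusing to write an empty result table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def write_run_report(report: dict, path: str | Path) -> None:
    """Write a JSON run report (processing/QC summaries) next to result CSVs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserialisable {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n", encoding="utf-8")
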