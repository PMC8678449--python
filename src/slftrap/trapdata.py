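"""Reading, validation and writing of long-format trap-count tables.

The canonical on-disk format is a tidy (long) RFC-4180 CSV with one row per
trap x observation date x instar.  Column order is fixed so that
``read_trap_csv`` inverts ``write_trap_csv`` exactly.  Wide files with one
count column per instar are accepted through the ``instar_wide`` entry of the
schema mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed column order of the canonical trap-count CSV.
CANONICAL_COLUMNS = [
    "site",
    "plot",
    "trap_id",
    "date",
    "instar",
    "count",
    "dbh_cm",
    "band_width_cm",
    "foam_width_cm",
    "treatment",
]

REQUIRED_COLUMNS = ["site", "trap_id", "date", "instar", "count"]

#: Valid instar codes: nymphal stages 1-4 plus the all-stage total.
VALID_INSTARS = frozenset({"1", "2", "3", "4", "combined"})

_KEY_COLUMNS = ["site", "plot", "trap_id", "date", "instar"]
_NUMERIC_COLUMNS = ["dbh_cm", "band_width_cm", "foam_width_cm"]
_STRING_DEFAULTS = {"plot": "", "treatment": "control"}


class TrapDataError(ValueError):
    """Base error for malformed trap-count data."""


class SchemaError(TrapDataError):
    """A required column is missing or the schema mapping is inconsistent."""


class ValidationError(TrapDataError):
    """Row-level contents violate the trap-record contract."""


@dataclass(eq=False)
class Dataset:
    """A validated collection of trap records plus free-form metadata.

    ``records`` is a :class:`pandas.DataFrame` with the canonical columns;
    ``date`` is held as ``datetime64[ns]`` (daily resolution), ``count`` as
    integer, ``instar`` as string codes from :data:`VALID_INSTARS`.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.records = self.records[CANONICAL_COLUMNS].reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.records.equals(other.records) and self.metadata == other.metadata

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dates(self) -> list[pd.Timestamp]:
        """Sorted unique observation dates."""
        return sorted(self.records["date"].unique())

    def subset(self, mask) -> "Dataset":
        """Dataset restricted to rows where ``mask`` holds."""
        return Dataset(self.records.loc[mask].reset_index(drop=True), dict(self.metadata))


def _validate_frame(df: pd.DataFrame, *, source: str = "<data>") -> pd.DataFrame:
    """Coerce dtypes and enforce row-level invariants, naming offending rows.

    Row numbers reported are 1-based positions in the input (header = row 1),
    matching what a user sees in a spreadsheet.
    """
    df = df.copy()
    rows = df.index.to_numpy() + 2  # +1 for header, +1 for 1-based

    for col, default in _STRING_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    # dates: strict ISO-8601
    parsed = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        raise ValidationError(
            f"{source}: unparseable ISO-8601 date(s) at row(s) {list(rows[bad.to_numpy()])}"
        )
    df["date"] = parsed.dt.normalize()

    # counts: non-negative integers
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna()
    if bad.any():
        raise ValidationError(
            f"{source}: non-numeric count(s) at row(s) {list(rows[bad.to_numpy()])}"
        )
    noninteger = (counts % 1 != 0).to_numpy()
    if noninteger.any():
        raise ValidationError(
            f"{source}: non-integer count(s) at row(s) {list(rows[noninteger])}"
        )
    negative = (counts < 0).to_numpy()
    if negative.any():
        raise ValidationError(
            f"{source}: negative count(s) at row(s) {list(rows[negative])}"
        )
    df["count"] = counts.astype(np.int64)

    df["instar"] = df["instar"].astype(str).str.strip()
    bad = ~df["instar"].isin(VALID_INSTARS)
    if bad.any():
        raise ValidationError(
            f"{source}: invalid instar code(s) at row(s) {list(rows[bad.to_numpy()])}; "
            f"valid codes are {sorted(VALID_INSTARS)}"
        )

    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col, default in _STRING_DEFAULTS.items():
        df[col] = df[col].fillna(default).astype(str)
        df.loc[df[col].isin({"nan", ""}) & (col == "treatment"), col] = default
    df["site"] = df["site"].astype(str)
    df["trap_id"] = df["trap_id"].astype(str)

    dup = df.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dup.any():
        raise ValidationError(
            f"{source}: duplicate (site, plot, trap_id, date, instar) key(s) "
            f"at row(s) {list(rows[dup.to_numpy()])}"
        )
    return df


def read_trap_csv(path, schema: Mapping[str, object] | None = None) -> Dataset:
    """Read a trap-count CSV into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file path.
    schema
        Optional mapping from canonical column names to the column names used
        in the file (e.g. ``{"trap_id": "tree"}``).  The special key
        ``"instar_wide"`` may map instar codes to per-instar count columns for
        wide input, in which case no ``instar``/``count`` columns are expected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trap-count file not found: {path}")
    schema = dict(schema or {})
    wide: Mapping[str, str] | None = schema.pop("instar_wide", None)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    rename = {v: k for k, v in schema.items() if isinstance(v, str)}
    raw = raw.rename(columns=rename)

    if wide:
        id_cols = [c for c in raw.columns if c not in wide.values()]
        missing = [c for c in wide.values() if c not in raw.columns]
        if missing:
            raise SchemaError(f"{path}: wide instar column(s) missing: {', '.join(missing)}")
        long = raw.melt(
            id_vars=id_cols,
            value_vars=list(wide.values()),
            var_name="_instar_col",
            value_name="count",
        )
        colmap = {v: k for k, v in wide.items()}
        long["instar"] = long["_instar_col"].map(colmap)
        raw = long.drop(columns="_instar_col")

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    df = _validate_frame(raw, source=str(path))
    return Dataset(df, metadata={"source": str(path)})


def write_trap_csv(ds: Dataset, path) -> Path:
    """Write a :class:`Dataset` as the canonical tidy CSV; returns the path."""
    path = Path(path)
    out = ds.records.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=CANONICAL_COLUMNS)
    return path


def from_records(df: pd.DataFrame, metadata: dict | None = None) -> Dataset:
    """Build a validated Dataset from an in-memory frame (long format)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return Dataset(_validate_frame(df), metadata=metadata or {})


def run_cli(argv) -> int:
    """Run the package CLI with the given argument tokens; returns exit status."""
    from .cli import run_cli as _run

    return _run(argv)


def ensure_combined(ds: Dataset) -> Dataset:
    """Return a Dataset in which every trap x date has a ``combined`` row.

    Explicitly stored combined rows win over rows derivable by summing the
    per-instar counts; a warning is logged when both are present.
    """
    df = ds.records
    per_instar = df[df["instar"] != "combined"]
    explicit = df[df["instar"] == "combined"]
    if per_instar.empty:
        return ds

    group_cols = ["site", "plot", "trap_id", "date"]
    derived = (
        per_instar.groupby(group_cols, as_index=False, sort=False)
        .agg(
            count=("count", "sum"),
            dbh_cm=("dbh_cm", "first"),
            band_width_cm=("band_width_cm", "first"),
            foam_width_cm=("foam_width_cm", "first"),
            treatment=("treatment", "first"),
        )
        .assign(instar="combined")
    )
    if not explicit.empty:
        exp_counts = explicit.set_index(group_cols)["count"]
        der_indexed = derived.set_index(group_cols)
        overlap_idx = der_indexed.index.intersection(exp_counts.index)
        if len(overlap_idx):
            disagree = (
                der_indexed.loc[overlap_idx, "count"] != exp_counts.loc[overlap_idx]
            ).sum()
            if disagree:
                logger.warning(
                    "explicit 'combined' rows disagree with per-instar sums for "
                    "%d trap-dates; keeping the explicit rows",
                    int(disagree),
                )
        derived = der_indexed.drop(index=overlap_idx).reset_index()
    merged = pd.concat([df, derived[CANONICAL_COLUMNS]], ignore_index=True)
    return Dataset(merged, dict(ds.metadata))
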