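"""CSV readers/writers, schema validation and the run manifest.

All tables are headered, comma-separated, UTF-8, ``.`` decimal CSV; an empty
field encodes a missing measurement (a qPCR reaction that never crossed
threshold).  Readers validate schemas up front and report offending columns
and row numbers, so a malformed file fails at the door rather than midway
through an analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import ConcordanceMatrix

__all__ = [
    "SchemaError",
    "CT_TABLE_COLUMNS",
    "PEAK_TABLE_COLUMNS",
    "CALLS_COLUMNS",
    "read_ct_table",
    "read_peak_table",
    "read_calls",
    "read_matrix",
    "write_table",
    "write_matrix",
    "RunManifest",
    "file_sha256",
]

CT_TABLE_COLUMNS = ["sample_id", "replicate_index", "ct_target", "ct_reference", "input_mass"]
PEAK_TABLE_COLUMNS = ["sample_id", "replicate_index", "area_target", "area_paralog"]
CALLS_COLUMNS = ["sample_id", "continuous_cn", "predicted_cn", "confidence", "method"]


class SchemaError(ValueError):
    """A table file does not match its documented schema."""


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df

def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _require_numeric(df: pd.DataFrame, columns, path, allow_missing=()) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col not in allow_missing and coerced.isna().any() and not bad.any():
            # genuinely empty fields in a column that must be present
            rows = (coerced.isna()).to_numpy().nonzero()[0]
            raise SchemaError(f"{path}: column {col!r} has missing values at row(s) {rows[:5] + 2}")
        if bad.any():
            rows = bad.to_numpy().nonzero()[0]
            raise SchemaError(
                f"{path}: column {col!r} is non-numeric at row(s) {(rows[:5] + 2).tolist()}"
            )
        df[col] = coerced
    return df


def read_ct_table(path) -> pd.DataFrame:
    """Read and validate a Ct table (``sample_id, replicate_index, ct_target,
    ct_reference, input_mass``); empty Ct fields become NaN (missing)."""
    df = _read_csv(path)
    _require_columns(df, CT_TABLE_COLUMNS, path)
    df = _require_numeric(
        df,
        ["replicate_index", "ct_target", "ct_reference", "input_mass"],
        path,
        allow_missing=("ct_target", "ct_reference"),
    )
    present = df[["ct_target", "ct_reference"]].to_numpy()
    with np.errstate(invalid="ignore"):
        out_of_range = (present <= 0) | (present > 40)
    if np.nansum(out_of_range) > 0:
        rows = np.unique(out_of_range.nonzero()[0])
        raise SchemaError(f"{path}: Ct values outside (0, 40] at row(s) {(rows[:5] + 2).tolist()}")
    return df[CT_TABLE_COLUMNS]


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate a PRT peak-area table."""
    df = _read_csv(path)
    _require_columns(df, PEAK_TABLE_COLUMNS, path)
    df = _require_numeric(df, ["replicate_index", "area_target", "area_paralog"], path)
    if (df[["area_target", "area_paralog"]].to_numpy() < 0).any():
        raise SchemaError(f"{path}: peak areas must be >= 0")
    return df[PEAK_TABLE_COLUMNS]


def read_calls(path) -> pd.DataFrame:
    """Read a calls table written by the qPCR or PRT caller."""
    df = _read_csv(path)
    _require_columns(df, ["sample_id", "continuous_cn", "predicted_cn"], path)
    df = _require_numeric(df, ["continuous_cn", "predicted_cn"], path)
    df["predicted_cn"] = df["predicted_cn"].astype(int)
    return df


def read_matrix(path, method_a: str = "A", method_b: str = "B") -> ConcordanceMatrix:
    """Read a pre-tabulated concordance matrix.

    Expected layout: first column holds method-A (row) copy-number labels,
    remaining column headers are method-B copy numbers; blank cells are zero
    counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    try:
        rows = [int(i) for i in df.index]
        cols = [int(c) for c in df.columns]
    except (TypeError, ValueError):
        raise SchemaError(f"{path}: row/column headers must be integer copy numbers") from None
    if min(rows + cols) < 0:
        raise SchemaError(f"{path}: copy-number labels must be >= 0")
    k_max = max(rows + cols)
    counts = np.zeros((k_max + 1, k_max + 1), dtype=int)
    values = df.fillna(0).to_numpy()
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            counts[r, c] = int(values[i, j])
    return ConcordanceMatrix(counts, method_a=method_a, method_b=method_b)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_matrix(matrix: ConcordanceMatrix, path) -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path)
    return path


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one pipeline run: every output directory gets one."""

    command: str
    config_hash: str
    seed: int
    input_files: list
    output_files: list
    timestamp: str = ""
    package_version: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        if not self.package_version:
            from . import __version__

            self.package_version = __version__

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
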