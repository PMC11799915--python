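"""Schema-checked readers and writers for the pipeline's flat tables.

Each schema fixes the header (exact column names and order), the column
dtypes and any row-level validation.  Malformed rows are reported with
their line number in the source file.  All tables are TSV except gel bands
and reporter wells, which are CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple
    dtypes: dict
    sep: str = "\t"
    row_check: Callable | None = None
    key_cols: tuple = ()


def _check_event_row(row) -> str | None:
    coords = [row["c1"], row["c2"], row["c3"], row["c4"]]
    if coords != sorted(coords):
        return f"coordinates not ascending: {coords}"
    if row["event_type"] not in ("SE", "RI", "MXE", "A5SS", "A3SS"):
        return f"unknown event_type {row['event_type']!r}"
    if row["inc_len"] <= 0 or row["skip_len"] <= 0:
        return "form lengths must be positive"
    for col in ("ijc", "sjc"):
        try:
            vals = [int(x) for x in str(row[col]).split(",")]
        except ValueError:
            return f"{col} is not a comma-separated integer list"
        if any(v < 0 for v in vals):
            return f"negative junction count in {col}"
    if not -1 <= row["delta_psi"] <= 1:
        return f"delta_psi outside [-1, 1]: {row['delta_psi']}"
    return None


def _check_band_row(row) -> str | None:
    if row["isoform"] not in ("included", "skipped"):
        return f"isoform must be included/skipped, got {row['isoform']!r}"
    if row["length_nt"] <= 0:
        return "length_nt must be positive"
    if row["volume"] < 0 or not np.isfinite(row["volume"]):
        return "volume must be finite and nonnegative"
    return None


SCHEMAS = {
    "deg": TableSchema(
        "deg",
        ("gene", "week", "log2FC", "pvalue", "padj"),
        {"gene": str, "week": int, "log2FC": float, "pvalue": float, "padj": float},
        key_cols=("gene", "week"),
    ),
    "de_result": TableSchema(
        "de_result",
        ("feature", "week", "log2FC", "pvalue", "padj", "direction"),
        {"feature": str, "week": int, "log2FC": float, "pvalue": float,
         "padj": float, "direction": str},
        key_cols=("feature", "week"),
    ),
    "category": TableSchema(
        "category",
        ("mirna", "significant_weeks", "category", "direction_consistent"),
        {"mirna": str, "significant_weeks": str, "category": str,
         "direction_consistent": str},
        key_cols=("mirna",),
    ),
    "target_db": TableSchema(
        "target_db",
        ("db", "mirna", "gene"),
        {"db": str, "mirna": str, "gene": str},
        key_cols=("db", "mirna", "gene"),
    ),
    "event": TableSchema(
        "event",
        ("gene", "event_type", "chrom", "strand", "c1", "c2", "c3", "c4",
         "ijc", "sjc", "inc_len", "skip_len", "psi_g1", "psi_g2",
         "delta_psi", "pvalue"),
        {"gene": str, "event_type": str, "chrom": str, "strand": str,
         "c1": int, "c2": int, "c3": int, "c4": int, "ijc": str, "sjc": str,
         "inc_len": int, "skip_len": int, "psi_g1": float, "psi_g2": float,
         "delta_psi": float, "pvalue": float},
        row_check=_check_event_row,
        key_cols=("gene", "event_type", "chrom", "strand", "c1", "c2", "c3", "c4"),
    ),
    "band": TableSchema(
        "band",
        ("sample", "group", "isoform", "volume", "length_nt"),
        {"sample": str, "group": str, "isoform": str, "volume": float,
         "length_nt": float},
        sep=",",
        row_check=_check_band_row,
        key_cols=("sample", "isoform"),
    ),
    "reporter": TableSchema(
        "reporter",
        ("well", "group", "renilla", "firefly"),
        {"well": str, "group": str, "renilla": float, "firefly": float},
        sep=",",
        key_cols=("well",),
    ),
}


class TableFormatError(ValueError):
    pass


def read_table(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read and validate a flat table against a named schema.

    The header must match the schema exactly (names and order); dtype
    coercion failures, duplicate keys and row-check violations raise
    :class:`TableFormatError` naming the offending line.
    """
    schema = SCHEMAS[schema_id]
    path = Path(path)
    df = pd.read_csv(path, sep=schema.sep, dtype=str, keep_default_na=False)
    if tuple(df.columns) != schema.columns:
        raise TableFormatError(
            f"{path}: header {tuple(df.columns)} does not match schema "
            f"{schema_id!r} {schema.columns}"
        )
    for col, dtype in schema.dtypes.items():
        if dtype is str:
            continue
        try:
            df[col] = df[col].astype(dtype)
        except ValueError as exc:
            for i, raw in enumerate(df[col]):
                try:
                    dtype(raw)
                except ValueError:
                    raise TableFormatError(
                        f"{path}, line {i + 2}: cannot parse {col}={raw!r} "
                        f"as {dtype.__name__}"
                    ) from exc
            raise
    if schema.key_cols:
        dup = df.duplicated(subset=list(schema.key_cols))
        if dup.any():
            line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
            raise TableFormatError(
                f"{path}, line {line}: duplicate key on {schema.key_cols}"
            )
    if schema.row_check is not None:
        for i, (_, row) in enumerate(df.iterrows()):
            msg = schema.row_check(row)
            if msg:
                raise TableFormatError(f"{path}, line {i + 2}: {msg}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema_id: str) -> Path:
    """Write a table in the named schema's column order and separator."""
    schema = SCHEMAS[schema_id]
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise TableFormatError(
            f"cannot write {schema_id!r}: missing columns {sorted(missing)}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[list(schema.columns)].to_csv(path, sep=schema.sep, index=False)
    return path


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a count matrix TSV (feature rows, `<cond>_w<week>_r<rep>` columns)."""
    from mirsplice.de import parse_sample_metadata

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise TableFormatError(f"{path}: duplicate feature ids")
    parse_sample_metadata(df.columns)  # validates the header contract
    if (df.to_numpy() < 0).any():
        raise TableFormatError(f"{path}: negative counts")
    return df
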