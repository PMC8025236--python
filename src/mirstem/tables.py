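"""Schema-checked tabular I/O for all pipeline stages.

All tables are TSV by default; CSV is auto-detected from a ``.csv``
extension and either dialect can be forced with ``sep``.  Files are UTF-8
with a header row and '.' decimal separator.  Missing values may be empty
fields or "NA".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# column name -> (dtype, nullable)
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "ct": {
        "assay_id": ("str", False),
        "sample_id": ("str", False),
        "group": ("str", False),
        "replicate": ("int", False),
        "ct": ("float", True),
        "is_housekeeping": ("bool", False),
    },
    "profile": {"gene_id": ("str", False), "log2fc": ("float", False)},
    "targets": {"gene_id": ("str", False), "context_score": ("float", True)},
    "ld": {
        "group": ("str", False),
        "dose": ("float", False),
        "n_tested": ("int", False),
        "n_responded": ("int", False),
    },
    "dose_response": {
        "group": ("str", False),
        "concentration_nM": ("float", False),
        "viability": ("float", False),
        "replicate": ("int", False),
    },
}

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path, schema: str | dict, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV stage table, validating against its schema.

    ``schema`` is either a key of ``SCHEMAS`` or a mapping
    column -> (dtype, nullable).  Errors report the offending column and
    1-based data row.
    """
    path = Path(path)
    spec = SCHEMAS[schema] if isinstance(schema, str) else schema
    raw = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str,
                      keep_default_na=False, na_values=["", "NA"])
    missing = [c for c in spec if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    out = pd.DataFrame(index=raw.index)
    for col, (dtype, nullable) in spec.items():
        series = raw[col]
        if not nullable and series.isna().any():
            row = int(series.index[series.isna()][0]) + 1
            raise SchemaError(f"{path}: missing value in column '{col}', row {row}")
        if dtype == "str":
            out[col] = series.astype("string").astype(object)
        elif dtype in ("float", "int"):
            converted = pd.to_numeric(series, errors="coerce")
            bad = series.notna() & converted.isna()
            if bad.any():
                row = int(series.index[bad][0]) + 1
                raise SchemaError(
                    f"{path}: unparseable value {series[bad].iloc[0]!r} "
                    f"in column '{col}', row {row}"
                )
            out[col] = converted.astype(float if dtype == "float" else "Int64")
            if dtype == "int" and not nullable:
                out[col] = out[col].astype(int)
        elif dtype == "bool":
            lowered = series.str.lower()
            bad = ~lowered.isin(_TRUE | _FALSE)
            if bad.any():
                row = int(series.index[bad][0]) + 1
                raise SchemaError(
                    f"{path}: unparseable boolean {series[bad].iloc[0]!r} "
                    f"in column '{col}', row {row}"
                )
            out[col] = lowered.isin(_TRUE)
        else:  # pragma: no cover - schema authoring error
            raise ValueError(f"unknown dtype {dtype!r} in schema")
    # keep any extra columns as strings, after the schema columns
    for col in raw.columns:
        if col not in out.columns:
            out[col] = raw[col]
    return out


def write_table(df: pd.DataFrame, path, sep: str | None = None) -> Path:
    """Write a stage table; round-trips through ``read_table`` losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_infer_sep(path, sep), index=False, na_rep="NA")
    return path
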