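"""Schema-checked TSV reading and writing for the pipeline artifacts.

All artifact tables are UTF-8 TSV with a header row, "." decimal
separator and no NA values in numeric result columns; write followed
by read is an identity on values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TableSchema", "read_table", "write_table",
           "EXPRESSION_SCHEMA", "CONTRAST_SCHEMA", "SELECTION_SCHEMA",
           "PROBE_SCHEMA", "TRUTH_SCHEMA", "CT_SCHEMA", "CATEGORY_SCHEMA"]


@dataclass(frozen=True)
class TableSchema:
    """Fixed leading columns (name -> "str"|"float"|"int") plus an
    optional tail of extra numeric columns (e.g. one per sample)."""

    name: str
    columns: dict = field(default_factory=dict)
    extra_numeric: bool = False
    optional: tuple = ()

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [
            c for c in self.columns
            if c not in df.columns and c not in self.optional
        ]
        if missing:
            raise ValueError(
                f"{self.name} table is missing required column(s): "
                + ", ".join(missing)
            )
        numeric = [c for c, k in self.columns.items()
                   if k in ("float", "int") and c in df.columns]
        if self.extra_numeric:
            numeric += [c for c in df.columns if c not in self.columns]
        for c in numeric:
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                raise ValueError(
                    f"{self.name} table column {c!r} holds non-numeric or NA values"
                )
            df[c] = vals.astype(int if self.columns.get(c) == "int" else float)
        return df


PROBE_SCHEMA = TableSchema(
    "probe matrix",
    {"probe_id": "str", "probeset_id": "str", "gene_symbol": "str",
     "position_index": "int"},
    extra_numeric=True,
    optional=("gene_symbol", "position_index"),
)
EXPRESSION_SCHEMA = TableSchema(
    "expression matrix",
    {"probeset_id": "str", "gene_symbol": "str"},
    extra_numeric=True,
    optional=("gene_symbol",),
)
CONTRAST_SCHEMA = TableSchema(
    "contrast MA",
    {"probeset_id": "str", "gene_symbol": "str", "A": "float", "M": "float"},
    optional=("gene_symbol",),
)
SELECTION_SCHEMA = TableSchema(
    "selection",
    {"probeset_id": "str", "gene_symbol": "str", "A": "float", "M": "float",
     "direction": "str", "row": "int", "col": "int", "hex_count": "int"},
    optional=("gene_symbol",),
)
TRUTH_SCHEMA = TableSchema(
    "truth",
    {"probeset_id": "str", "contrast_id": "int", "true_direction": "str",
     "true_log2_shift": "float"},
)
CT_SCHEMA = TableSchema(
    "Ct",
    {"sample_id": "str", "group": "str", "target_ct": "float",
     "reference_ct": "float"},
    optional=("sample_id",),
)
CATEGORY_SCHEMA = TableSchema("category map", {"category": "str", "gene": "str"})


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV artifact and validate it against ``schema``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return schema.validate(df)


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> Path:
    """Write a TSV artifact (UTF-8, '.' decimals, no index)."""
    if schema is not None:
        numeric = [c for c, k in schema.columns.items()
                   if k in ("float", "int") and c in df.columns]
        if schema.extra_numeric:
            numeric += [c for c in df.columns if c not in schema.columns]
        for c in numeric:
            if df[c].isna().any() or not np.isfinite(df[c].to_numpy(float)).all():
                raise ValueError(f"refusing to write NA/non-finite values in {c!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path
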