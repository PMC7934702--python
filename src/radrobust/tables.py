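"""Feature-table schemas, validation and CSV round-tripping.

A feature table is a pandas DataFrame whose annotation columns identify the
sample (``sample_id`` + ``group`` for cohorts, ``lesion_id`` + ``condition_id``
for phantom acquisitions) and whose remaining columns are numeric feature
values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ANNOTATION_COLUMNS",
    "feature_columns",
    "validate_feature_table",
    "read_feature_table",
    "write_feature_table",
]


class SchemaError(ValueError):
    """A feature table violates its declared schema."""


ANNOTATION_COLUMNS = ("sample_id", "group", "lesion_id", "condition_id", "timepoint")

_SCHEMAS = {
    # schema name -> (key columns, other required columns)
    "cohort": (("sample_id",), ("group",)),
    "retest": (("sample_id",), ()),
    "phantom": (("lesion_id", "condition_id"), ()),
}

_GROUP_LEVELS = {"wildtype", "mutant"}


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The non-annotation columns of a feature table, in order."""
    return [c for c in table.columns if c not in ANNOTATION_COLUMNS]


def validate_feature_table(table: pd.DataFrame, schema: str) -> pd.DataFrame:
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    keys, required = _SCHEMAS[schema]
    for col in keys + required:
        if col not in table.columns:
            raise SchemaError(f"{schema} table is missing required column {col!r}")
    for col in keys + required:
        if table[col].isna().any():
            row = int(table.index[table[col].isna()][0])
            raise SchemaError(f"annotation column {col!r} has a missing value at row {row}")
    dup = table.duplicated(subset=list(keys))
    if dup.any():
        row = int(table.index[dup][0])
        raise SchemaError(f"duplicate key {tuple(keys)} at row {row}")
    if schema == "cohort":
        bad = ~table["group"].isin(_GROUP_LEVELS)
        if bad.any():
            row = int(table.index[bad][0])
            raise SchemaError(
                f"column 'group' has value {table['group'].iloc[row]!r} at row {row}; "
                f"expected one of {sorted(_GROUP_LEVELS)}"
            )
    features = feature_columns(table)
    if not features:
        raise SchemaError(f"{schema} table has no feature columns")
    for col in features:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any():
            row = int(table.index[bad][0])
            raise SchemaError(
                f"feature column {col!r} has a non-numeric or non-finite value at row {row}"
            )
        table[col] = values.astype(float)
    return table


def read_feature_table(path: str, schema: str) -> pd.DataFrame:
    """Read a CSV feature table and validate it against ``schema``."""
    table = pd.read_csv(path)
    return validate_feature_table(table, schema)


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)
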