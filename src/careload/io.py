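"""CSV schemas, strict table validation, and survival-data preparation.

All tabular interchange uses headered UTF-8 CSV with the exact column names
of the four experiment schemas; missing values are forbidden.  Validation
failures name the offending column and row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TableSchema",
    "BEHAVIOR_SCHEMA",
    "EGG_SCHEMA",
    "BEAN_SCHEMA",
    "FECUNDITY_SCHEMA",
    "validate_table",
    "read_table",
    "write_table",
    "prepare_survival",
]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    integer: tuple[str, ...]
    nonnegative: tuple[str, ...]
    bounds: tuple[tuple[str, str], ...] = ()   # (col, upper-bound col) pairs


BEHAVIOR_SCHEMA = TableSchema(
    name="behavior",
    columns=("trial_id", "treatment", "line_id", "cross_type",
             "run", "time_index", "n_on_uninfested", "n_females"),
    integer=("trial_id", "run", "time_index", "n_on_uninfested", "n_females"),
    nonnegative=("n_on_uninfested",),
    bounds=(("n_on_uninfested", "n_females"),),
)

EGG_SCHEMA = TableSchema(
    name="eggs",
    columns=("trial_id", "treatment", "line_id", "cross_type",
             "run", "eggs_uninfested", "eggs_infested"),
    integer=("trial_id", "run", "eggs_uninfested", "eggs_infested"),
    nonnegative=("eggs_uninfested", "eggs_infested"),
)

BEAN_SCHEMA = TableSchema(
    name="beans",
    columns=("duo_id", "line_id", "cross_type",
             "n_focal_eggs", "n_competitor_eggs", "n_focal_emerged"),
    integer=("duo_id", "n_focal_eggs", "n_competitor_eggs", "n_focal_emerged"),
    nonnegative=("n_focal_eggs", "n_competitor_eggs", "n_focal_emerged"),
    bounds=(("n_focal_emerged", "n_focal_eggs"),),
)

FECUNDITY_SCHEMA = TableSchema(
    name="fecundity",
    columns=("female_id", "cross_label", "hatched_eggs"),
    integer=("female_id", "hatched_eggs"),
    nonnegative=("hatched_eggs",),
)


def validate_table(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    """Check columns, types, missing values and range invariants."""
    got = list(df.columns)
    if got != list(schema.columns):
        raise SchemaError(
            f"{schema.name}: expected columns {list(schema.columns)}, got {got}")
    for col in schema.columns:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"{schema.name}: missing value in column "
                              f"{col!r} at row {row}")
    for col in schema.integer:
        vals = df[col]
        num = pd.to_numeric(vals, errors="coerce")
        if num.isna().any():
            row = int(df.index[num.isna()][0])
            raise SchemaError(f"{schema.name}: non-numeric value in integer "
                              f"column {col!r} at row {row}")
        if not np.allclose(num, np.round(num)):
            row = int(df.index[~np.isclose(num, np.round(num))][0])
            raise SchemaError(f"{schema.name}: non-integer value in column "
                              f"{col!r} at row {row}")
    for col in schema.nonnegative:
        num = pd.to_numeric(df[col])
        if (num < 0).any():
            row = int(df.index[num < 0][0])
            raise SchemaError(f"{schema.name}: negative value in column "
                              f"{col!r} at row {row}")
    for col, upper in schema.bounds:
        bad = pd.to_numeric(df[col]) > pd.to_numeric(df[upper])
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"{schema.name}: {col} exceeds {upper} "
                              f"at row {row}")
    return df


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate one of the four CSV schemas (header required)."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != list(schema.columns):
        raise SchemaError(
            f"{schema.name}: header mismatch in {path.name}: expected "
            f"{list(schema.columns)}, got {list(df.columns)}")
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, schema: TableSchema) -> None:
    validate_table(df, schema)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def prepare_survival(beans: pd.DataFrame,
                     max_focal_eggs: int = 3) -> tuple[pd.DataFrame, dict]:
    """Clean the bean table for survival modelling.

    Beans with more than ``max_focal_eggs`` focal eggs are discarded (they
    are rare and unevenly distributed across cross types), as are beans that
    received no focal eggs (no survival outcome to model).  The competition
    covariate experienced by each focal egg is attached:
    C = n_focal_eggs + n_competitor_eggs - 1, so a singleton egg on an
    uninfested seed has C = 0 and the admissible maximum is C = 6.

    Returns the cleaned table and a filter log with removed-row counts by
    rule and cross type (rows_in = rows_out + rows removed).
    """
    validate_table(beans, BEAN_SCHEMA)
    n_in = len(beans)
    over = beans["n_focal_eggs"] > max_focal_eggs
    zero = beans["n_focal_eggs"] == 0

    def by_cross(mask):
        return {str(k): int(v) for k, v in
                beans.loc[mask, "cross_type"].value_counts().items()}

    kept = beans.loc[~(over | zero)].copy()
    kept["C"] = (kept["n_focal_eggs"] + kept["n_competitor_eggs"] - 1).astype(float)
    log = {
        "rows_in": int(n_in),
        "rows_out": int(len(kept)),
        "removed_over_max_focal": {
            "total": int(over.sum()), "by_cross_type": by_cross(over)},
        "removed_no_focal_eggs": {
            "total": int(zero.sum()), "by_cross_type": by_cross(zero)},
        "max_focal_eggs": int(max_focal_eggs),
    }
    assert log["rows_in"] == log["rows_out"] + int(over.sum()) + int(zero.sum())
    return kept, log
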