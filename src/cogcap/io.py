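"""CSV schemas and strict readers/writers for trial and subject tables.

Fixed dialect: comma-separated, UTF-8, header row, "." decimal, empty
string for a missing RT (no-response trials).  Round-trips are bit-exact
for the integer columns and float-exact via repr for RTs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

ANT_SCHEMA = {
    "subject_id": str, "block": int, "alerting": int, "orienting": str,
    "congruency": str, "responded": int, "rt_ms": float, "correct": int,
}
MFT_SCHEMA = {
    "subject_id": str, "block": int, "set_size": int, "majority_n": int,
    "minority_n": int, "exposure_s": float, "responded": int, "rt_ms": float,
    "correct": int,
}
SUBJECT_SCHEMA = {
    "subject_id": str, "group": str, "sex": str, "age": float, "school": int,
    "snap_inatt_n": int, "snap_hyper_n": int, "asq_parent": int, "asq_teacher": int,
}
SCHEMAS = {"ant": ANT_SCHEMA, "mft": MFT_SCHEMA, "subjects": SUBJECT_SCHEMA}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _validate_columns(df: pd.DataFrame, schema: dict, where: str) -> None:
    required = set(schema)
    have = set(df.columns)
    missing = sorted(required - have)
    extra = sorted(have - required)
    problems = []
    if missing:
        problems.append(f"missing columns: {missing}")
    if extra:
        problems.append(f"unexpected columns: {extra}")
    if problems:
        raise SchemaError(f"{where}: " + "; ".join(problems))


def read_trials(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a trial/subject CSV, validating columns and types.

    An empty ``rt_ms`` with ``responded = 0`` is a no-response trial and
    parses to NaN; an empty RT on a responded trial is a schema violation.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype={"subject_id": str})
    _validate_columns(df, spec, str(path))
    for col, typ in spec.items():
        if typ is int:
            bad = df[df[col].isna()]
            if len(bad):
                raise SchemaError(
                    f"{path}: column {col!r} empty at line {int(bad.index[0]) + 2}")
            df[col] = df[col].astype(int)
        elif typ is float and col != "rt_ms":
            df[col] = df[col].astype(float)
    if "rt_ms" in df.columns and "responded" in df.columns:
        bad = df[(df["responded"] == 1) & (df["rt_ms"].isna())]
        if len(bad):
            raise SchemaError(
                f"{path}: responded trial without rt_ms at line {int(bad.index[0]) + 2}")
    # column order fixed by the schema
    return df[list(spec)]


def write_trials(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a table in the fixed CSV dialect after schema validation."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    _validate_columns(df, spec, str(path))
    out = df[list(spec)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, na_rep="")


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Round-trip equality check tolerant of float repr."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        if a[col].dtype.kind in "fc" or b[col].dtype.kind in "fc":
            av = a[col].astype(float).to_numpy()
            bv = b[col].astype(float).to_numpy()
            both_nan = np.isnan(av) & np.isnan(bv)
            if not np.all(both_nan | np.isclose(av, bv, rtol=0, atol=1e-9)):
                return False
        else:
            if not (a[col].astype(str) == b[col].astype(str)).all():
                return False
    return True
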