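"""Cohort table schema, validation, and delimited-text round-trip.

A cohort is an ordinary :class:`pandas.DataFrame` with one row per patient
and the fixed column set in :data:`COHORT_COLUMNS`. Missing values are
``NaN`` in memory and empty fields on disk (comma-delimited, UTF-8, one
header row).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "patient_id",
    "histology",
    "age",
    "receptor_subtype",
    "stage",
    "grade",
    "treatment",
    "method",
    "ctc_per_ml",
    "dtc_per_ml",
    "drfs_time",
    "drfs_event",
    "bcss_time",
    "bcss_event",
]

HISTOLOGIES = ("ILC", "IDC")
SUBTYPES = ("HR+HER2-", "HR-/HER2-", "HER2+")
STAGES = (1, 2, 3)
GRADES = (1, 2, 3)
TREATMENTS = ("primary_surgery", "neoadjuvant")
METHODS = ("IEFC", "CellSearch")
ENDPOINTS = ("drfs", "bcss")


class CohortFormatError(ValueError):
    """A cohort table violates the documented schema."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort frame against the schema; return it unchanged.

    Raises :class:`CohortFormatError` naming the offending column and, where
    identifiable, the 1-based data row number.
    """
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise CohortFormatError(f"unknown column(s): {unknown}")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"missing column(s): {missing_cols}")

    dup = df["patient_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise CohortFormatError(f"duplicated patient_id at row {row}")
    if df["patient_id"].isna().any():
        row = int(np.flatnonzero(df["patient_id"].isna().to_numpy())[0]) + 1
        raise CohortFormatError(f"missing patient_id at row {row}")

    def bad_rows(mask, col, what):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise CohortFormatError(f"{what} in column {col!r} at row {row}")

    for col, allowed in [
        ("histology", HISTOLOGIES),
        ("receptor_subtype", SUBTYPES),
        ("treatment", TREATMENTS),
        ("method", METHODS),
    ]:
        vals = df[col]
        bad_rows(vals.notna() & ~vals.isin(allowed), col, "unparseable value")

    for col, allowed in [("stage", STAGES), ("grade", GRADES)]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_rows(df[col].notna() & ~vals.isin(allowed), col, "unparseable value")

    for col in ("ctc_per_ml", "dtc_per_ml"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_rows(df[col].notna() & vals.isna(), col, "unparseable value")
        bad_rows(vals.notna() & (vals < 0), col, "negative count")

    bad_rows(df["age"].notna() & (pd.to_numeric(df["age"], errors="coerce") <= 0),
             "age", "non-positive value")

    for ep in ENDPOINTS:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        t = pd.to_numeric(df[tcol], errors="coerce")
        bad_rows(df[tcol].isna() | (t <= 0), tcol, "missing or non-positive time")
        e = pd.to_numeric(df[ecol], errors="coerce")
        bad_rows(~e.isin([0, 1]), ecol, "event indicator not 0/1")

    return df


def _normalise_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str)
    for col in ("age", "ctc_per_ml", "dtc_per_ml", "drfs_time", "bcss_time",
                "stage", "grade"):
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    for col in ("drfs_event", "bcss_event"):
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(int)
    return out[COHORT_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a validated cohort to a comma-delimited UTF-8 file.

    Missing values are written as empty fields; floats keep full (repr)
    precision so the round trip is exact.
    """
    df = validate_cohort(_normalise_dtypes(df))
    out = df.copy()
    # integers-as-floats (stage/grade) serialise without trailing .0
    for col in ("stage", "grade"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort written by :func:`write_cohort`."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str}, encoding="utf-8")
    except Exception as exc:  # delimited-parse failure
        raise CohortFormatError(f"cannot parse cohort file {path}: {exc}") from exc
    validate_cohort(df)
    return _normalise_dtypes(df)
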