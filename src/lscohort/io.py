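"""Cohort CSV input/output with dialect handling and row validation.

The data dictionary (`COLUMN_TYPES`) documents the expected columns and
storage units.  German-locale files (semicolon separator, decimal comma)
are supported through the `decimal`/`sep` arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units

logger = logging.getLogger(__name__)

#: column -> (dtype, unit) data dictionary for cohort CSVs
COLUMN_TYPES = {
    "id": ("string", ""),
    "sex": ("category:male|female", ""),
    "age": ("float", "years"),
    "height": ("float", "cm"),
    "weight": ("float", "kg"),
    "albumin": ("float", "g/L"),
    "total_cholesterol": ("float", "mmol/L"),
    "hdl": ("float", "mmol/L"),
    "ldl": ("float", "mmol/L"),
    "triglycerides": ("float", "mmol/L"),
    "lymphocytes": ("float", "10^9/L"),
    "systolic_bp": ("float", "mmHg"),
    "diastolic_bp": ("float", "mmHg"),
    "diabetes": ("bool", ""),
    "smoker": ("bool", ""),
    "diet_subscore": ("float", "points"),
    "pa_subscore": ("float", "points"),
    "smoking_subscore": ("float", "points"),
    "alcohol_g_per_day": ("float", "g/day"),
    "alcohol_subscore": ("float", "points"),
    "mace": ("bool", ""),
    "survival_months": ("float", "months"),
    "event": ("bool", ""),
    "total_cholesterol_fu": ("float", "mmol/L"),
    "hdl_fu": ("float", "mmol/L"),
    "triglycerides_fu": ("float", "mmol/L"),
}

REQUIRED_COLUMNS = ("id", "sex", "age")

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False, "ja": True, "nein": False}


@dataclass
class CohortTable:
    """Typed cohort frame plus a row/column validation report."""

    frame: pd.DataFrame
    n_rows_dropped: int = 0
    missing_counts: pd.Series = field(default_factory=pd.Series)
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().map(_BOOL_MAP)


def read_cohort_csv(path, sep: str = ",", decimal: str = ".") -> CohortTable:
    """Read a cohort CSV into typed columns with validation.

    Unparseable numeric entries become NaN and are counted; rows invalid at
    the record level (non-positive height/weight, unknown sex) are dropped
    and counted.  Albumin magnitude is checked against the g/L plausibility
    window.
    """
    raw = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str,
                      skipinitialspace=True)
    missing_required = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_required:
        raise ValueError(f"missing required column(s): {missing_required}")

    df = pd.DataFrame(index=raw.index)
    warns = []
    for col in raw.columns:
        spec = COLUMN_TYPES.get(col)
        if spec is None:
            df[col] = raw[col]
            continue
        kind = spec[0]
        if kind == "float":
            values = raw[col]
            if decimal != ".":
                values = values.str.replace(decimal, ".", regex=False)
            df[col] = pd.to_numeric(values, errors="coerce")
            bad = raw[col].notna() & df[col].isna()
            if bad.any():
                warns.append(f"{col}: {int(bad.sum())} unparseable value(s)")
        elif kind == "bool":
            df[col] = _coerce_bool(raw[col])
        elif kind.startswith("category"):
            allowed = kind.split(":", 1)[1].split("|")
            df[col] = raw[col].str.strip().str.lower()
            df.loc[~df[col].isin(allowed), col] = None
        else:
            df[col] = raw[col]

    valid = df["sex"].notna() & df["age"].notna()
    for col in ("height", "weight"):
        if col in df.columns:
            valid &= df[col].isna() | (df[col] > 0)
    dropped = int((~valid).sum())
    if dropped:
        warns.append(f"{dropped} invalid row(s) excluded")
        logger.warning("excluded %d invalid rows from %s", dropped, path)
    df = df[valid].reset_index(drop=True)

    if "albumin" in df.columns and not units.check_albumin_unit(
            df["albumin"], context=f"{path}: albumin"):
        warns.append("albumin magnitude outside plausible g/L range")

    missing_counts = df.isna().sum()
    for w in warns:
        logger.warning("%s", w)
    return CohortTable(frame=df, n_rows_dropped=dropped,
                       missing_counts=missing_counts, warnings=warns)


def write_cohort_csv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a (scored) cohort frame; NaN as empty field."""
    df.to_csv(path, index=False, float_format=float_format)


def frame_checksum(df: pd.DataFrame) -> str:
    """Stable content hash of a frame (used by the pipeline manifest)."""
    import hashlib

    payload = df.to_csv(index=False, float_format="%.10g").encode()
    return hashlib.sha256(payload).hexdigest()
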