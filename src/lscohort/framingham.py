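"""Framingham 10-year coronary heart disease risk (categorical point model).

Implements the sex-specific 1998 point tables: points are assigned for age
band, total (or LDL) cholesterol band, HDL band, JNC blood-pressure
category, diabetes and smoking; the point total maps to a tabulated 10-year
CHD risk in percent.  Cholesterol inputs arrive in mmol/L and are converted
to mg/dL internally.

The tables cover ages 30-74; ages outside that window are clamped to the
nearest covered band, mirroring common calculator behaviour.  Point totals
outside the tabulated range are clamped to the nearest tabulated row, so the
returned risk saturates at the table's extremes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import units
from .tables import load_framingham_tables, load_score_bands

__all__ = ["framingham_points", "framingham_risk", "framingham_category",
           "framingham_risk_frame"]

_REQUIRED = ("sex", "age", "hdl", "systolic_bp", "diastolic_bp",
             "diabetes", "smoker")


def _points_from_bands(value, band_table):
    edges = np.array([row[0] for row in band_table], dtype=float)
    pts = np.array([row[1] for row in band_table], dtype=float)
    idx = np.clip(np.searchsorted(edges, value, side="right") - 1, 0, len(pts) - 1)
    return pts[idx]


def _bp_category(sbp, dbp) -> np.ndarray:
    tab = load_framingham_tables()
    cat_s = np.searchsorted(np.asarray(tab["bp_sbp_edges"], dtype=float),
                            sbp, side="right")
    cat_d = np.searchsorted(np.asarray(tab["bp_dbp_edges"], dtype=float),
                            dbp, side="right")
    return np.maximum(cat_s, cat_d)


def framingham_points(
    sex: str,
    age: float,
    total_cholesterol: float | None,
    hdl: float,
    systolic_bp: float,
    diastolic_bp: float,
    diabetes: bool,
    smoker: bool,
    mode: str = "tc",
    ldl: float | None = None,
) -> int:
    """Point total for one participant (cholesterol inputs in mmol/L)."""
    if mode not in ("tc", "ldl"):
        raise ValueError(f"mode must be 'tc' or 'ldl', got {mode!r}")
    tab = load_framingham_tables()[mode][sex]
    chol = ldl if mode == "ldl" else total_cholesterol
    if chol is None or not np.isfinite(chol):
        raise ValueError(f"{mode} cholesterol required")
    chol_mgdl = float(units.cholesterol_mmol_to_mgdl(chol))
    hdl_mgdl = float(units.cholesterol_mmol_to_mgdl(hdl))
    pts = (
        _points_from_bands(np.clip(age, 30, 74), tab["age"])
        + _points_from_bands(chol_mgdl, tab["cholesterol"])
        + _points_from_bands(hdl_mgdl, tab["hdl"])
        + np.asarray(tab["bp_points"], dtype=float)[
            int(_bp_category(systolic_bp, diastolic_bp))
        ]
        + (tab["diabetes"] if diabetes else 0)
        + (tab["smoker"] if smoker else 0)
    )
    return int(round(float(pts)))


def _risk_from_points(points, risk_map) -> np.ndarray:
    keys = np.array(sorted(risk_map), dtype=int)
    vals = np.array([risk_map[k] for k in keys], dtype=float)
    idx = np.clip(np.searchsorted(keys, points, side="right") - 1, 0,
                  len(keys) - 1)
    return vals[idx]


def framingham_risk(
    sex: str,
    age: float,
    total_cholesterol: float | None,
    hdl: float,
    systolic_bp: float,
    diastolic_bp: float,
    diabetes: bool,
    smoker: bool,
    mode: str = "tc",
    ldl: float | None = None,
) -> float:
    """10-year CHD risk in percent from the point tables."""
    pts = framingham_points(sex, age, total_cholesterol, hdl, systolic_bp,
                            diastolic_bp, diabetes, smoker, mode=mode, ldl=ldl)
    risk_map = load_framingham_tables()[mode][sex]["risk"]
    return float(_risk_from_points(np.asarray([pts]), risk_map)[0])


def framingham_risk_frame(df: pd.DataFrame, mode: str = "tc") -> pd.Series:
    """Vectorized risk for a cohort frame; rows with missing inputs get NaN."""
    chol_col = "ldl" if mode == "ldl" else "total_cholesterol"
    need = list(_REQUIRED) + [chol_col]
    cols = {}
    for c in need:
        if c not in df.columns:
            return pd.Series(np.nan, index=df.index, name="framingham_risk")
        cols[c] = df[c]
    sexes = cols["sex"].astype(str)
    numeric = {
        c: pd.to_numeric(cols[c], errors="coerce").to_numpy(dtype=float)
        for c in (chol_col, "age", "hdl", "systolic_bp", "diastolic_bp")
    }
    flags = {
        c: cols[c].map(lambda v: bool(v) if pd.notna(v) else np.nan).to_numpy()
        for c in ("diabetes", "smoker")
    }
    complete = (
        sexes.isin(["male", "female"]).to_numpy()
        & np.all([np.isfinite(numeric[c]) for c in numeric], axis=0)
        & pd.notna(flags["diabetes"]) & pd.notna(flags["smoker"])
    )

    out = np.full(len(df), np.nan)
    tables = load_framingham_tables()
    bp_cat = _bp_category(numeric["systolic_bp"], numeric["diastolic_bp"])
    for sex in ("male", "female"):
        mask = complete & (sexes.to_numpy() == sex)
        if not mask.any():
            continue
        tab = tables[mode][sex]
        pts = (
            _points_from_bands(np.clip(numeric["age"][mask], 30, 74), tab["age"])
            + _points_from_bands(
                units.cholesterol_mmol_to_mgdl(numeric[chol_col][mask]),
                tab["cholesterol"])
            + _points_from_bands(
                units.cholesterol_mmol_to_mgdl(numeric["hdl"][mask]),
                tab["hdl"])
            + np.asarray(tab["bp_points"], dtype=float)[bp_cat[mask]]
            + np.where(flags["diabetes"][mask].astype(bool), tab["diabetes"], 0)
            + np.where(flags["smoker"][mask].astype(bool), tab["smoker"], 0)
        )
        out[mask] = _risk_from_points(np.round(pts).astype(int), tab["risk"])
    return pd.Series(out, index=df.index, name="framingham_risk")


def framingham_category(risk_percent: float) -> str:
    """Sehestedt risk bands: <5 low, [5,10) low-moderate, [10,20]
    moderate-high, >20 high."""
    if not 0 <= risk_percent <= 100:
        raise ValueError(f"risk must be within [0, 100], got {risk_percent}")
    cats = load_score_bands()["framingham_categories"]
    if risk_percent < cats["low_max"]:
        return "low"
    if risk_percent < cats["low_moderate_max"]:
        return "low_moderate"
    if risk_percent <= cats["moderate_high_max"]:
        return "moderate_high"
    return "high"
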