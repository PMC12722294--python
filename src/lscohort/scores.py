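"""Clinical score calculators: Lifestyle Score, CONUT, PNI, NRI.

All calculators exist in scalar form (explicit unit contracts in the
signatures) and as a vectorized :func:`score_cohort` that appends the full
score panel to a cohort DataFrame.  The Framingham risk model lives in
:mod:`lscohort.framingham`.

Unit contracts: albumin g/L, cholesterol mmol/L, lymphocytes 10^9 cells/L,
height cm, weight kg.  The PNI is defined on albumin in g/dL and lymphocytes
per mm^3; the conversion from storage units happens internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd

from . import units
from .framingham import framingham_category, framingham_risk_frame
from .schemes import DEFAULT_SCHEMES, TercileScheme
from .tables import load_score_bands

__all__ = [
    "ParticipantRecord",
    "ScorePanel",
    "lifestyle_score",
    "ls_category",
    "ls_excluding_smoking",
    "alcohol_subscore_band",
    "conut_score",
    "conut_group",
    "pni_score",
    "pni_group",
    "lorenz_ideal_weight",
    "nri_score",
    "nri_group",
    "score_panel",
    "score_cohort",
]


@dataclass
class ParticipantRecord:
    """One participant's raw fields; optional fields default to None/NaN."""

    id: str
    sex: str  # 'male' | 'female'
    age: float  # years
    height: float | None = None  # cm
    weight: float | None = None  # kg
    albumin: float | None = None  # g/L
    total_cholesterol: float | None = None  # mmol/L
    hdl: float | None = None  # mmol/L
    ldl: float | None = None  # mmol/L
    triglycerides: float | None = None  # mmol/L
    lymphocytes: float | None = None  # 10^9 cells/L
    systolic_bp: float | None = None  # mmHg
    diastolic_bp: float | None = None  # mmHg
    diabetes: bool | None = None
    smoker: bool | None = None
    diet_subscore: float | None = None
    pa_subscore: float | None = None
    smoking_subscore: float | None = None
    alcohol_g_per_day: float | None = None
    alcohol_subscore: float | None = None
    survival_months: float | None = None
    event: bool | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("height", "weight"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("albumin", "lymphocytes", "survival_months",
                     "diet_subscore", "pa_subscore", "smoking_subscore",
                     "alcohol_subscore", "alcohol_g_per_day"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


@dataclass
class ScorePanel:
    """Computed scores and category labels for one participant.

    Fields are individually None when their inputs were missing, so one
    missing lab only excludes the participant from the affected analyses.
    """

    ls: float | None = None
    ls_tercile: str | None = None
    conut: int | None = None
    conut_group: str | None = None
    pni: float | None = None
    pni_group: str | None = None
    nri: float | None = None
    nri_group: str | None = None
    framingham_risk: float | None = None
    framingham_category: str | None = None


def _missing(*values) -> bool:
    return any(
        v is None or (isinstance(v, (float, np.floating)) and np.isnan(v))
        for v in values
    )


# ---------------------------------------------------------------------------
# Lifestyle Score

def lifestyle_score(diet: float, pa: float, smoking: float, alcohol: float) -> float:
    """Sum of the diet, physical-activity, smoking and alcohol sub-scores.

    Lower is healthier; with the default sub-score schema the total spans
    3-66.  Returns NaN when any sub-score is missing (complete-case rule).
    """
    if _missing(diet, pa, smoking, alcohol):
        return float("nan")
    for name, v in (("diet", diet), ("pa", pa), ("smoking", smoking),
                    ("alcohol", alcohol)):
        if v < 0:
            raise ValueError(f"{name} sub-score must be >= 0, got {v}")
    return float(diet + pa + smoking + alcohol)


def ls_excluding_smoking(diet: float, pa: float, alcohol: float) -> float:
    """Lifestyle Score variant without the smoking sub-score (diet+PA+alcohol)."""
    if _missing(diet, pa, alcohol):
        return float("nan")
    return float(diet + pa + alcohol)


def ls_category(ls: float, scheme: TercileScheme | None = None) -> str | None:
    """Fixed-cut-off tercile of the Lifestyle Score (<=21 / 22-32 / >32)."""
    scheme = scheme or DEFAULT_SCHEMES["ls"]
    return scheme.categorize(ls)


def alcohol_subscore_band(intake_g_per_day: float, sex: str) -> str:
    """'penalized' when daily intake exceeds the sex-specific threshold.

    Thresholds follow the German Nutrition Society position: 10 g/day for
    women and 20 g/day for men; intake at or below the threshold is not
    penalized.
    """
    if intake_g_per_day < 0:
        raise ValueError(f"alcohol intake must be >= 0, got {intake_g_per_day}")
    thresholds = load_score_bands()["alcohol_thresholds_g_per_day"]
    if sex not in thresholds:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return "penalized" if intake_g_per_day > thresholds[sex] else "not_penalized"


# ---------------------------------------------------------------------------
# CONUT

def _band_lookup(values, band_table) -> np.ndarray:
    """Points for values against a [(lower_edge, points), ...] band table.

    The first row's edge may be NaN (catch-all lowest band); edges ascend
    and are closed below.
    """
    edges = np.array([row[0] for row in band_table[1:]], dtype=float)
    points = np.array([row[1] for row in band_table], dtype=float)
    arr = np.asarray(values, dtype=float)
    idx = np.searchsorted(edges, arr, side="right")
    out = points[idx]
    out[~np.isfinite(arr)] = np.nan
    return out


def conut_score(albumin: float, cholesterol: float, lymphocytes: float) -> float:
    """CONUT total (0-12 points) from albumin g/L, total cholesterol mmol/L
    and lymphocyte count 10^9/L; higher means worse nutritional status.

    Band point values are configuration data (``data/score_bands.yaml``).
    Returns NaN when any lab is missing.
    """
    if _missing(albumin, cholesterol, lymphocytes):
        return float("nan")
    if min(albumin, cholesterol, lymphocytes) < 0:
        raise ValueError("CONUT labs must be >= 0")
    bands = load_score_bands()["conut"]
    total = (
        _band_lookup([albumin], bands["albumin_g_per_l"])
        + _band_lookup([cholesterol], bands["total_cholesterol_mmol_per_l"])
        + _band_lookup([lymphocytes], bands["lymphocytes_1e9_per_l"])
    )
    return float(total[0])


def conut_group(conut: float) -> str | None:
    """Risk grouping of the CONUT total: 0 low, 1-2 moderate, >=3 high."""
    if _missing(conut):
        return None
    if not 0 <= conut <= 12:
        raise ValueError(f"CONUT must be within [0, 12], got {conut}")
    groups = load_score_bands()["conut_groups"]
    if conut <= groups["low_max"]:
        return "low"
    return "moderate" if conut <= groups["moderate_max"] else "high"


# ---------------------------------------------------------------------------
# PNI

def pni_score(albumin: float, lymphocytes: float) -> float:
    """Prognostic Nutritional Index; lower = higher malnutrition risk.

    Defined as ``10 x albumin[g/dL] + 0.005 x lymphocytes[cells/mm^3]``;
    inputs arrive in storage units (g/L, 10^9/L) and are converted here.
    """
    if _missing(albumin, lymphocytes):
        return float("nan")
    alb_gdl = float(units.albumin_g_per_l_to_g_per_dl(albumin))
    lymph_mm3 = float(units.lymphocytes_1e9_to_per_mm3(lymphocytes))
    return 10.0 * alb_gdl + 0.005 * lymph_mm3


def pni_group(pni: float, scheme: TercileScheme | None = None) -> str | None:
    """PNI risk tercile: >56.35 T1 (low risk), 53.25-56.35 T2, <53.25 T3."""
    scheme = scheme or DEFAULT_SCHEMES["pni"]
    return scheme.categorize(pni)


# ---------------------------------------------------------------------------
# NRI

def lorenz_ideal_weight(height: float, sex: str) -> float:
    """Ideal body weight (kg) by the Lorenz formula.

    Men: (height-100) - (height-150)/4; women: (height-100) - (height-150)/2.5.
    Heights at or below 150 cm are outside the formula's intended regime;
    the arithmetic is still returned but with a warning.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if height <= 0:
        raise ValueError(f"height must be > 0, got {height}")
    if height < 150:
        warnings.warn(
            f"height {height} cm below 150: Lorenz ideal weight extrapolated",
            UserWarning,
            stacklevel=2,
        )
    divisor = 4.0 if sex == "male" else 2.5
    return (height - 100.0) - (height - 150.0) / divisor


def nri_score(albumin: float, weight: float, ideal_weight: float) -> float:
    """Nutritional Risk Index: 1.489 x albumin[g/L] + 41.7 x weight/ideal.

    The weight ratio is deliberately not capped at 1 (the classic index caps
    current/usual weight; with the Lorenz ideal weight in the denominator,
    ratios above 1 are meaningful and required for the observed score range).
    """
    if _missing(albumin, weight, ideal_weight):
        return float("nan")
    if ideal_weight <= 0:
        raise ValueError(f"ideal weight must be > 0, got {ideal_weight}")
    return 1.489 * albumin + 41.7 * (weight / ideal_weight)


def nri_group(nri: float, scheme: TercileScheme | None = None) -> str | None:
    """NRI risk tercile: >122.8 T1 (low risk), 115.2-122.8 T2, <115.2 T3."""
    scheme = scheme or DEFAULT_SCHEMES["nri"]
    return scheme.categorize(nri)


# ---------------------------------------------------------------------------
# Panel

def score_panel(
    record: ParticipantRecord,
    schemes: Mapping[str, TercileScheme] | None = None,
    framingham_mode: str = "tc",
) -> ScorePanel:
    """Compute every score and category for one participant.

    Missing inputs null the affected panel fields only.
    """
    row = record.to_series().to_frame().T
    scored = score_cohort(row, schemes=schemes, framingham_mode=framingham_mode)
    r = scored.iloc[0]

    def _val(col, cast=float):
        v = r[col]
        if pd.isna(v):
            return None
        return cast(v)

    return ScorePanel(
        ls=_val("ls"),
        ls_tercile=_val("ls_tercile", str),
        conut=_val("conut", int),
        conut_group=_val("conut_group", str),
        pni=_val("pni"),
        pni_group=_val("pni_group", str),
        nri=_val("nri"),
        nri_group=_val("nri_group", str),
        framingham_risk=_val("framingham_risk"),
        framingham_category=_val("framingham_category", str),
    )


def score_cohort(
    df: pd.DataFrame,
    schemes: Mapping[str, TercileScheme] | None = None,
    framingham_mode: str = "tc",
) -> pd.DataFrame:
    """Append the score panel to a cohort frame (vectorized, order-preserving).

    Adds: bmi, ideal_weight, ls, ls_no_smoking, ls_tercile, conut,
    conut_group, pni, pni_group, nri, nri_group, framingham_risk,
    framingham_category.  Rows missing the inputs of a given score get NaN
    for that score only.
    """
    schemes = dict(DEFAULT_SCHEMES, **(schemes or {}))
    bands = load_score_bands()
    out = df.copy()

    units.check_albumin_unit(out.get("albumin", np.nan), context="albumin")

    height = pd.to_numeric(out["height"], errors="coerce")
    weight = pd.to_numeric(out["weight"], errors="coerce")
    out["bmi"] = weight / (height / 100.0) ** 2

    subs = [
        pd.to_numeric(out[c], errors="coerce")
        for c in ("diet_subscore", "pa_subscore", "smoking_subscore",
                  "alcohol_subscore")
    ]
    out["ls"] = subs[0] + subs[1] + subs[2] + subs[3]
    out["ls_no_smoking"] = subs[0] + subs[1] + subs[3]
    out["ls_tercile"] = schemes["ls"].categorize_values(out["ls"])

    alb = pd.to_numeric(out["albumin"], errors="coerce").to_numpy()
    chol = pd.to_numeric(out["total_cholesterol"], errors="coerce").to_numpy()
    lymph = pd.to_numeric(out["lymphocytes"], errors="coerce").to_numpy()
    conut_bands = bands["conut"]
    out["conut"] = (
        _band_lookup(alb, conut_bands["albumin_g_per_l"])
        + _band_lookup(chol, conut_bands["total_cholesterol_mmol_per_l"])
        + _band_lookup(lymph, conut_bands["lymphocytes_1e9_per_l"])
    )
    grp = bands["conut_groups"]
    out["conut_group"] = pd.Categorical(
        np.select(
            [out["conut"].isna(), out["conut"] <= grp["low_max"],
             out["conut"] <= grp["moderate_max"]],
            [None, "low", "moderate"],
            default="high",
        ),
        categories=["low", "moderate", "high"],
        ordered=True,
    )

    out["pni"] = 10.0 * (alb / 10.0) + 0.005 * (lymph * 1000.0)
    out["pni_group"] = schemes["pni"].categorize_values(out["pni"])

    is_male = out["sex"].astype(str).to_numpy() == "male"
    divisor = np.where(is_male, 4.0, 2.5)
    hv = height.to_numpy()
    out["ideal_weight"] = (hv - 100.0) - (hv - 150.0) / divisor
    out["nri"] = 1.489 * alb + 41.7 * (weight.to_numpy() / out["ideal_weight"].to_numpy())
    out["nri_group"] = schemes["nri"].categorize_values(out["nri"])

    out["framingham_risk"] = framingham_risk_frame(out, mode=framingham_mode)
    out["framingham_category"] = pd.Categorical(
        [framingham_category(v) if np.isfinite(v) else None
         for v in out["framingham_risk"].to_numpy(dtype=float)],
        categories=["low", "low_moderate", "moderate_high", "high"],
        ordered=True,
    )
    return out
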