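"""Centralized unit conversions and plausibility gates for laboratory values.

Storage units throughout the package: albumin g/L, cholesterol fractions
mmol/L, lymphocytes 10^9 cells/L, height cm, weight kg, survival time months.
Scores that are defined on other units (PNI on g/dL albumin and cells/mm^3,
Framingham on mg/dL lipids) convert internally through this module.
"""

from __future__ import annotations

import warnings

import numpy as np

#: mg/dL per mmol/L for cholesterol and its fractions.
CHOLESTEROL_MGDL_PER_MMOL = 38.67

#: Plausible range of serum albumin in g/L; values in g/dL magnitude (~4.6)
#: trip this gate, catching the classic unit mix-up.
ALBUMIN_PLAUSIBLE_G_PER_L = (20.0, 60.0)


def cholesterol_mmol_to_mgdl(x):
    """Convert cholesterol (total, HDL or LDL) from mmol/L to mg/dL."""
    return np.asarray(x, dtype=float) * CHOLESTEROL_MGDL_PER_MMOL


def albumin_g_per_l_to_g_per_dl(x):
    return np.asarray(x, dtype=float) / 10.0


def lymphocytes_1e9_to_per_mm3(x):
    """10^9 cells/L equals 1000 cells/mm^3."""
    return np.asarray(x, dtype=float) * 1000.0


def check_albumin_unit(values, context: str = "albumin") -> bool:
    """Warn when albumin values look like g/dL rather than the expected g/L.

    Returns True when the (non-missing) median falls inside the plausible
    g/L window, False otherwise.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return True
    med = float(np.median(arr))
    lo, hi = ALBUMIN_PLAUSIBLE_G_PER_L
    if not lo <= med <= hi:
        warnings.warn(
            f"{context}: median {med:.2f} outside plausible g/L range "
            f"[{lo}, {hi}] - check that albumin is supplied in g/L, not g/dL",
            UserWarning,
            stacklevel=2,
        )
        return False
    return True
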