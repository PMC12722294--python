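"""Tercile schemes: mapping a continuous score to ordered T1/T2/T3 categories.

Two directions occur in practice.  For scores where a *high* value is
unfavourable (the Lifestyle Score), the printed convention is that both cut
points belong to the lower category: ``<= lower`` is T1, ``lower < x <=
upper`` is T2, ``> upper`` is T3.  For the protective nutritional indices
(PNI, NRI) a *low* value is unfavourable and both printed boundaries belong
to the moderate band: ``> upper`` is T1 (low risk), ``lower <= x <= upper``
is T2, ``< lower`` is T3 (high risk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import load_score_bands

TERCILE_LABELS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class TercileScheme:
    """Named pair of cut points with a direction and boundary convention."""

    name: str
    lower: float
    upper: float
    direction: str = "higher_is_worse"  # or "lower_is_worse"
    #: textual record of which side each cut is closed on
    boundary_rule: str = field(default="", compare=False)
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not self.lower <= self.upper:
            raise ValueError(
                f"{self.name}: boundaries must be ordered, got "
                f"({self.lower}, {self.upper})"
            )
        if self.direction not in ("higher_is_worse", "lower_is_worse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.boundary_rule:
            rule = (
                "T1 <= lower < T2 <= upper < T3"
                if self.direction == "higher_is_worse"
                else "T3 < lower <= T2 <= upper < T1"
            )
            object.__setattr__(self, "boundary_rule", rule)
        if self.lower == self.upper and not self.degenerate:
            object.__setattr__(self, "degenerate", True)

    def categorize(self, value: float) -> str | None:
        """Map one finite value to 'T1'/'T2'/'T3' (None for missing)."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if self.direction == "higher_is_worse":
            if value <= self.lower:
                return "T1"
            return "T2" if value <= self.upper else "T3"
        if value > self.upper:
            return "T1"
        return "T2" if value >= self.lower else "T3"

    def categorize_values(self, values) -> pd.Categorical:
        """Vectorized :meth:`categorize`; NaN stays missing."""
        arr = np.asarray(values, dtype=float)
        out = np.full(arr.shape, None, dtype=object)
        ok = np.isfinite(arr)
        if self.direction == "higher_is_worse":
            out[ok & (arr <= self.lower)] = "T1"
            out[ok & (arr > self.lower) & (arr <= self.upper)] = "T2"
            out[ok & (arr > self.upper)] = "T3"
        else:
            out[ok & (arr > self.upper)] = "T1"
            out[ok & (arr >= self.lower) & (arr <= self.upper)] = "T2"
            out[ok & (arr < self.lower)] = "T3"
        return pd.Categorical(out, categories=list(TERCILE_LABELS), ordered=True)


def _scheme_from_config(name: str) -> TercileScheme:
    cfg = load_score_bands()["tercile_schemes"][name]
    return TercileScheme(
        name=name.upper(),
        lower=float(cfg["lower"]),
        upper=float(cfg["upper"]),
        direction=cfg["direction"],
    )


#: Fixed published cut-offs.
LS_SCHEME = _scheme_from_config("ls")
PNI_SCHEME = _scheme_from_config("pni")
NRI_SCHEME = _scheme_from_config("nri")

DEFAULT_SCHEMES = {"ls": LS_SCHEME, "pni": PNI_SCHEME, "nri": NRI_SCHEME}
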