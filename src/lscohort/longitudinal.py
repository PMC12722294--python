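"""Paired baseline-to-follow-up lipid analysis across Lifestyle terciles.

Differences follow the convention ``baseline - follow-up``: a positive mean
difference means the value declined over time.  The reported SD of the
difference is the independence approximation
``sqrt(SD_baseline^2 + SD_followup^2)`` used in the source tables; the
statistically exact paired SD is also computed per participant.  Within-
tercile change is tested with the paired Wilcoxon signed-rank test (Pratt
handling of zero differences; exact null distribution for small samples
without zeros or ties), and changes are compared *between* terciles with
rank-sum tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["sd_of_difference", "paired_wilcoxon", "paired_difference_summary",
           "between_tercile_change_test", "longitudinal_report"]

#: variable -> (baseline column, follow-up column)
DEFAULT_PAIRS = {
    "total_cholesterol": ("total_cholesterol", "total_cholesterol_fu"),
    "hdl": ("hdl", "hdl_fu"),
    "triglycerides": ("triglycerides", "triglycerides_fu"),
}


def sd_of_difference(sd_base: float, sd_follow: float) -> float:
    """Euclidean combination sqrt(sd_base^2 + sd_follow^2).

    This treats the two waves as independent, so it overstates the true
    paired SD when baseline and follow-up are positively correlated; it is
    reproduced exactly as the source tables print it.
    """
    if sd_base < 0 or sd_follow < 0:
        raise ValueError("standard deviations must be >= 0")
    return float(np.hypot(sd_base, sd_follow))


def paired_wilcoxon(base, follow, exact_below: int = 25) -> float:
    """p-value of the paired Wilcoxon signed-rank test (Pratt zeros).

    Uses the exact null distribution for fewer than `exact_below` pairs
    when there are no zero differences or ties, otherwise the normal
    approximation with tie correction.  Identical series give p = 1.
    """
    b = np.asarray(base, dtype=float)
    f = np.asarray(follow, dtype=float)
    diff = b - f
    if len(diff) < 2:
        raise ValueError("need >= 2 pairs")
    if np.all(diff == 0):
        return 1.0
    has_zeros = np.any(diff == 0)
    nonzero = diff[diff != 0]
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = ("exact" if len(diff) < exact_below and not has_zeros
              and not has_ties else "approx")
    res = stats.wilcoxon(b, f, zero_method="pratt", method=method,
                         correction=False)
    return float(res.pvalue)


def paired_difference_summary(df: pd.DataFrame, base_col: str, fu_col: str,
                              tercile_col: str = "ls_tercile") -> pd.DataFrame:
    """Per-tercile paired summary of one variable.

    Columns: tercile, n, mean_base, sd_base, mean_follow, sd_follow,
    mean_diff (baseline - follow-up), sd_diff_approx (independence
    formula), sd_diff (exact paired SD), p (paired Wilcoxon).  Terciles
    with fewer than two complete pairs are reported null.
    """
    rows = []
    data = df[[tercile_col, base_col, fu_col]].dropna()
    levels = (list(df[tercile_col].cat.categories)
              if isinstance(df[tercile_col].dtype, pd.CategoricalDtype)
              else sorted(df[tercile_col].dropna().unique()))
    for lvl in levels:
        sub = data[data[tercile_col] == lvl]
        b = sub[base_col].to_numpy(dtype=float)
        f = sub[fu_col].to_numpy(dtype=float)
        if len(sub) < 2:
            rows.append({"tercile": lvl, "n": len(sub), "mean_base": np.nan,
                         "sd_base": np.nan, "mean_follow": np.nan,
                         "sd_follow": np.nan, "mean_diff": np.nan,
                         "sd_diff_approx": np.nan, "sd_diff": np.nan,
                         "p": np.nan})
            continue
        diff = b - f
        sd_b, sd_f = b.std(ddof=1), f.std(ddof=1)
        rows.append({
            "tercile": lvl,
            "n": len(sub),
            "mean_base": b.mean(),
            "sd_base": sd_b,
            "mean_follow": f.mean(),
            "sd_follow": sd_f,
            "mean_diff": diff.mean(),
            "sd_diff_approx": sd_of_difference(sd_b, sd_f),
            "sd_diff": diff.std(ddof=1),
            "p": paired_wilcoxon(b, f),
        })
    return pd.DataFrame(rows)


def between_tercile_change_test(df: pd.DataFrame, base_col: str, fu_col: str,
                                tercile_col: str = "ls_tercile") -> pd.DataFrame:
    """Rank-sum comparisons of per-person change between tercile pairs.

    Returns rows T1 vs T2, T1 vs T3, T2 vs T3 with the rank-sum statistic
    and p; pairs involving an empty (or singleton) tercile are null.
    """
    data = df[[tercile_col, base_col, fu_col]].dropna()
    changes = {}
    for lvl, sub in data.groupby(tercile_col, observed=False):
        changes[lvl] = (sub[base_col] - sub[fu_col]).to_numpy(dtype=float)
    levels = (list(df[tercile_col].cat.categories)
              if isinstance(df[tercile_col].dtype, pd.CategoricalDtype)
              else sorted(changes))
    populated = sum(len(changes.get(lvl, ())) >= 2 for lvl in levels)
    if populated < 2:
        warnings.warn("fewer than two populated terciles", UserWarning,
                      stacklevel=2)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = changes.get(levels[i], np.array([]))
            b = changes.get(levels[j], np.array([]))
            if len(a) < 2 or len(b) < 2:
                stat, p = np.nan, np.nan
            else:
                stat, p = stats.ranksums(a, b)
            rows.append({"comparison": f"{levels[i]} vs {levels[j]}",
                         "statistic": float(stat) if stat == stat else np.nan,
                         "p": float(p) if p == p else np.nan})
    return pd.DataFrame(rows)


def longitudinal_report(df: pd.DataFrame, pairs: dict | None = None,
                        tercile_col: str = "ls_tercile") -> dict:
    """Full paired-lipid report across terciles for several variables.

    Returns ``{"summary": per-tercile paired summaries,
    "between": between-tercile change comparisons}``.
    """
    pairs = pairs or DEFAULT_PAIRS
    summaries, betweens = [], []
    for var, (b, f) in pairs.items():
        if b not in df.columns or f not in df.columns:
            continue
        summary = paired_difference_summary(df, b, f, tercile_col)
        summary.insert(0, "variable", var)
        summaries.append(summary)
        between = between_tercile_change_test(df, b, f, tercile_col)
        between.insert(0, "variable", var)
        betweens.append(between)
    if not summaries:
        raise ValueError("no paired columns found")
    return {"summary": pd.concat(summaries, ignore_index=True),
            "between": pd.concat(betweens, ignore_index=True)}
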