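"""Group stratification, cross-tabulation, adjusted comparisons, correlations.

Reproduces the descriptive analysis surface of the cohort study: empirical
tercile construction, score-by-score contingency tables with row
percentages, chi-square independence tests, ANCOVA-style adjusted group
comparisons with Tukey HSD post-hoc contrasts on adjusted means, rank tests
for skewed outcomes, and the correlation panel between the Lifestyle Score
(full and smoking-excluded) and the Framingham risk score.

p-values are reported raw throughout: the analysis policy is two-sided
alpha = 0.05 with no multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .schemes import TercileScheme

__all__ = [
    "CrossTab",
    "GroupComparison",
    "empirical_terciles",
    "cross_tabulate",
    "chi_square_independence",
    "adjusted_group_comparison",
    "rank_test",
    "score_correlations",
]


def empirical_terciles(values, name: str = "score") -> TercileScheme:
    """Tercile scheme from the empirical 1/3 and 2/3 quantiles.

    Boundary values join the lower tercile (the ``<= cut`` convention).
    All-identical input yields a degenerate single-group scheme, flagged on
    the returned object.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 3:
        raise ValueError(f"need >= 3 non-missing values, got {arr.size}")
    # order-statistic (type-1) quantiles keep the cuts on observed values,
    # so boundary scores land in the lower tercile like the printed cut-offs
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3], method="inverted_cdf")
    if q1 == q2:
        warnings.warn(
            f"{name}: degenerate tercile scheme (identical quantiles)",
            UserWarning, stacklevel=2)
    return TercileScheme(name=name, lower=float(q1), upper=float(q2),
                         direction="higher_is_worse")


@dataclass
class CrossTab:
    """Contingency table with row percentages (denominator = row total)."""

    counts: pd.DataFrame
    row_pct: pd.DataFrame
    n_missing: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def cross_tabulate(rows, cols, row_name: str = "rows",
                   col_name: str = "cols") -> CrossTab:
    """Counts and row percentages for two aligned category sequences.

    Pairs with any missing label are dropped (and counted in
    ``n_missing``).
    """
    r = pd.Series(rows).reset_index(drop=True)
    c = pd.Series(cols).reset_index(drop=True)
    if len(r) != len(c):
        raise ValueError("row and column sequences must be the same length")
    if len(r) == 0:
        raise ValueError("empty input")
    keep = r.notna() & c.notna()
    counts = pd.crosstab(r[keep], c[keep], dropna=False)
    counts.index.name, counts.columns.name = row_name, col_name
    if counts.size == 0:
        raise ValueError("no complete pairs")
    row_tot = counts.sum(axis=1)
    row_pct = counts.div(row_tot.replace(0, np.nan), axis=0) * 100.0
    return CrossTab(counts=counts, row_pct=row_pct,
                    n_missing=int((~keep).sum()))


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Accepts a :class:`CrossTab`, DataFrame or array of counts; returns
    (statistic, df, p).  Warns when any expected count is below 5.
    """
    counts = table.counts if isinstance(table, CrossTab) else table
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    stat, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count below 5 in at least one cell",
                      UserWarning, stacklevel=2)
    return float(stat), int(dof), float(p)


@dataclass
class GroupComparison:
    """ANCOVA result for a group factor plus Tukey post-hoc contrasts."""

    statistic: float       # F statistic of the group factor
    df: tuple              # (df_num, df_den)
    p_value: float
    adjusted_means: pd.Series
    tukey: pd.DataFrame = field(repr=False)  # pair, estimate, se, q, p_adj
    n: int = 0


def adjusted_group_comparison(df: pd.DataFrame, outcome: str, group: str,
                              covariates=("age", "sex")) -> GroupComparison:
    """ANCOVA (OLS with the group coded as a factor) plus Tukey HSD.

    The group-factor F test comes from a type-II ANOVA on the fitted model;
    pairwise contrasts compare covariate-adjusted group means with p-values
    from the studentized range distribution, the standard Tukey HSD
    correction.
    """
    cols = [outcome, group, *covariates]
    data = df[cols].dropna().copy()
    levels = sorted(pd.Series(data[group]).astype(str).unique())
    if len(levels) < 2 or (data.groupby(group, observed=True)[outcome]
                           .count() < 2).any():
        raise ValueError("need >= 2 groups with >= 2 observations each")
    data[group] = data[group].astype(str)

    cov_terms = " + ".join(
        f"C({c})" if not pd.api.types.is_numeric_dtype(data[c]) else c
        for c in covariates)
    formula = f"{outcome} ~ C({group})"
    if cov_terms:
        formula += " + " + cov_terms
    try:
        model = sm.formula.ols(formula, data=data).fit()
    except Exception as exc:  # pragma: no cover - rare numerical failure
        raise ValueError(f"could not fit ANCOVA model: {exc}") from exc
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        names = model.model.exog_names
        raise ValueError(f"singular design matrix; check columns {names}")

    anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc[f"C({group})"]
    df_num = float(row["df"])
    df_den = float(model.df_resid)

    # Adjusted (marginal) means: group effects at covariate means.
    params = model.params
    base = params.get("Intercept", 0.0)
    cov_contrib = 0.0
    for c in covariates:
        if pd.api.types.is_numeric_dtype(data[c]):
            cov_contrib += params.get(c, 0.0) * data[c].mean()
        else:
            props = data[c].astype(str).value_counts(normalize=True)
            for lvl, pr in props.items():
                cov_contrib += params.get(f"C({c})[T.{lvl}]", 0.0) * pr
    adj = {}
    for lvl in levels:
        adj[lvl] = base + params.get(f"C({group})[T.{lvl}]", 0.0) + cov_contrib
    adjusted_means = pd.Series(adj, name="adjusted_mean")

    cov = model.cov_params()
    k = len(levels)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            name_i = f"C({group})[T.{levels[i]}]"
            name_j = f"C({group})[T.{levels[j]}]"
            contrast = pd.Series(0.0, index=params.index)
            if name_i in contrast.index:
                contrast[name_i] = 1.0
            if name_j in contrast.index:
                contrast[name_j] -= 1.0
            est = float(params @ contrast)
            se = float(np.sqrt(contrast @ cov @ contrast))
            q = abs(est) / se * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, df_den))
            pairs.append({"pair": f"{levels[i]} vs {levels[j]}",
                          "estimate": est, "se": se, "q": q, "p_adj": p_adj})

    return GroupComparison(
        statistic=float(row["F"]), df=(df_num, df_den),
        p_value=float(row["PR(>F)"]), adjusted_means=adjusted_means,
        tukey=pd.DataFrame(pairs), n=len(data))


def rank_test(df_or_outcome, group=None, outcome: str | None = None):
    """Kruskal-Wallis for >= 3 groups, Wilcoxon rank-sum for 2.

    Call either with (df, group=<col>, outcome=<col>) or with an outcome
    sequence and an aligned group sequence.  Returns (statistic, p).
    A constant outcome yields p = 1 with a warning; groups of size < 2 are
    an error.
    """
    if isinstance(df_or_outcome, pd.DataFrame):
        data = df_or_outcome[[outcome, group]].dropna()
        samples = [g[outcome].to_numpy(dtype=float)
                   for _, g in data.groupby(group, observed=True)]
    else:
        s = pd.DataFrame({"y": df_or_outcome, "g": group}).dropna()
        samples = [g["y"].to_numpy(dtype=float)
                   for _, g in s.groupby("g", observed=True)]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        warnings.warn("constant outcome: rank test degenerate, p = 1",
                      UserWarning, stacklevel=2)
        return 0.0, 1.0
    if len(samples) == 2:
        stat, p = stats.ranksums(samples[0], samples[1])
    else:
        stat, p = stats.kruskal(*samples)
    return float(stat), float(p)


def _corr_row(x, y, method: str, label: str) -> dict:
    s = pd.DataFrame({"x": x, "y": y}).dropna()
    n = len(s)
    if n < 3:
        warnings.warn(f"{label}: fewer than 3 complete pairs", UserWarning,
                      stacklevel=3)
        return {"pair": label, "method": method, "estimate": np.nan,
                "p_value": np.nan, "n": n}
    func = {"spearman": stats.spearmanr, "pearson": stats.pearsonr,
            "kendall": stats.kendalltau}[method]
    est, p = func(s["x"], s["y"])
    return {"pair": label, "method": method, "estimate": float(est),
            "p_value": float(p), "n": n}


def score_correlations(scored: pd.DataFrame) -> pd.DataFrame:
    """Correlation panel of the scored cohort.

    Spearman and Pearson between the Framingham risk and: the full LS, the
    smoking-excluded LS, and each lifestyle sub-score; Kendall's tau
    (appropriate for the heavily tied discrete sub-scores) between the diet
    and smoking sub-scores and each malnutrition index.
    """
    fs = scored["framingham_risk"]
    rows = []
    for col, label in [("ls", "LS vs FS"),
                       ("ls_no_smoking", "LS (no smoking) vs FS"),
                       ("diet_subscore", "diet vs FS"),
                       ("pa_subscore", "physical activity vs FS"),
                       ("smoking_subscore", "smoking vs FS"),
                       ("alcohol_subscore", "alcohol vs FS")]:
        for method in ("spearman", "pearson"):
            rows.append(_corr_row(scored[col], fs, method, label))
    for sub, sub_label in [("diet_subscore", "diet"),
                           ("smoking_subscore", "smoking")]:
        for idx in ("conut", "pni", "nri"):
            rows.append(_corr_row(scored[sub], scored[idx], "kendall",
                                  f"{sub_label} vs {idx.upper()}"))
    return pd.DataFrame(rows)
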