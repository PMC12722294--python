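"""Mortality analysis: Kaplan-Meier, Cox models, diagnostics, age interaction.

The Cox partial-likelihood solver and the product-limit estimator delegate
to lifelines (Efron handling of tied event times - survival time is stored
with month granularity, so ties are the rule, not the exception).  The
pieces specific to this analysis are implemented here: factor coding with a
declared reference level (tercile models use T3/high as reference so the
healthier terciles get protective hazard ratios), z-standardization of the
Lifestyle Score, the age-group effect-modification procedure (nested-model
likelihood-ratio test with 2 degrees of freedom plus stratum-specific
fits), and the Schoenfeld proportional-hazards diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats

__all__ = [
    "CoxFit",
    "KMResult",
    "AgeInteractionResult",
    "km_curves",
    "cox_fit",
    "schoenfeld_check",
    "standardize_ls",
    "age_group",
    "age_interaction_analysis",
    "interaction_lrt",
]

AGE_GROUP_LABELS = ("<60", "60-69", ">=70")


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients, hazard ratios, Wald CIs and p-values."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    model: CoxPHFitter = field(repr=False)
    design: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "HR": self.hazard_ratios,
            "HR_lower_95": self.ci_lower,
            "HR_upper_95": self.ci_upper,
            "p": self.p_values,
        })


def _build_design(df: pd.DataFrame, covariates, duration_col, event_col,
                  factors=None) -> pd.DataFrame:
    """Numeric design frame; factor columns dummy-coded against their
    declared reference level."""
    factors = factors or {}
    cols = {}
    for c in covariates:
        if c in factors:
            ref = str(factors[c])
            series = df[c].astype(str).where(df[c].notna())
            levels = sorted(x for x in series.dropna().unique())
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} absent from column {c!r} "
                    f"(levels: {levels})")
            for lvl in levels:
                if lvl == ref:
                    continue
                cols[f"{c}[{lvl}]"] = (series == lvl).astype(float) \
                    .where(series.notna())
        else:
            cols[c] = pd.to_numeric(df[c], errors="coerce")
    design = pd.DataFrame(cols, index=df.index)
    design[duration_col] = pd.to_numeric(df[duration_col], errors="coerce")
    design[event_col] = df[event_col].astype(bool)
    return design.dropna()


def cox_fit(df: pd.DataFrame, covariates, duration_col: str = "survival_months",
            event_col: str = "event", factors: dict | None = None,
            alpha: float = 0.05) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with reference-coded factors.

    `factors` maps a column name to its reference level, e.g.
    ``{"ls_tercile": "T3"}`` reproduces the "3rd tercile (reference)"
    convention.  Raises on non-convergence (with the lifelines iteration
    context attached) and warns on suspected complete separation.
    """
    design = _build_design(df, covariates, duration_col, event_col, factors)
    n = len(design)
    n_events = int(design[event_col].sum())
    if n_events < 1:
        raise ValueError("need at least one event to fit a Cox model")
    # Newton-Raphson at lifelines' default step size can overshoot into a
    # non-positive-definite Hessian on dummy-heavy designs (it then either
    # raises or reports non-convergence); fit with damped steps, walking
    # the step size down until the optimizer genuinely converges.
    last_exc = None
    cph = None
    for step_size in (0.5, 0.25, 0.1, 0.05):
        candidate = CoxPHFitter(alpha=alpha)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                candidate.fit(design, duration_col=duration_col,
                              event_col=event_col,
                              fit_options={"step_size": step_size,
                                           "precision": 1e-10})
            not_converged = any(
                "failed to converge" in str(w.message) for w in caught)
            finite = (np.isfinite(candidate.params_).all()
                      and np.isfinite(candidate.standard_errors_).all())
            if finite and not not_converged:
                cph = candidate
                break
            last_exc = RuntimeError(
                f"optimizer did not converge at step size {step_size}")
        except Exception as exc:
            last_exc = exc
    if cph is None:
        raise RuntimeError(
            f"Cox model did not converge: {last_exc}") from last_exc
    if (cph.params_.abs() > 10).any():
        warnings.warn("very large coefficient: possible complete separation",
                      UserWarning, stacklevel=2)
    ci = np.exp(cph.confidence_intervals_)
    return CoxFit(
        coefficients=cph.params_.copy(),
        hazard_ratios=np.exp(cph.params_),
        ci_lower=ci.iloc[:, 0].rename(None),
        ci_upper=ci.iloc[:, 1].rename(None),
        p_values=cph.summary["p"].copy(),
        log_likelihood=float(cph.log_likelihood_),
        n=n,
        n_events=n_events,
        model=cph,
        design=design,
    )


def schoenfeld_check(fit: CoxFit, time_transform: str = "rank"):
    """Scaled-Schoenfeld proportional-hazards diagnostics.

    Returns (per_covariate_p: Series, global_p: float).  The global value
    combines the per-covariate tests with a Sidak correction - conservative
    under positive dependence between covariates.  With fewer than two
    events the test is undefined and (None, None) is returned with a
    warning.
    """
    if fit.n_events < 2:
        warnings.warn("too few events for Schoenfeld diagnostics",
                      UserWarning, stacklevel=2)
        return None, None
    res = proportional_hazard_test(fit.model, fit.design,
                                   time_transform=time_transform)
    per_cov = res.summary["p"].copy()
    if isinstance(per_cov.index, pd.MultiIndex):
        per_cov.index = per_cov.index.get_level_values(0)
    k = len(per_cov)
    global_p = float(1.0 - (1.0 - per_cov.min()) ** k)
    return per_cov, global_p


@dataclass
class KMResult:
    """Per-group product-limit estimates on a monthly grid plus log-rank."""

    table: pd.DataFrame  # columns: group, month, at_risk, survival
    logrank_stat: float | None
    logrank_p: float | None


def km_curves(df: pd.DataFrame, group_col: str | None = None,
              duration_col: str = "survival_months",
              event_col: str = "event") -> KMResult:
    """Kaplan-Meier survival per group with at-risk counts at whole months.

    With no events anywhere the curves are flat at 1 and the log-rank test
    is undefined (None with a warning).
    """
    data = df[[duration_col, event_col]
              + ([group_col] if group_col else [])].dropna()
    if len(data) == 0:
        raise ValueError("no usable observations")
    durations = data[duration_col].to_numpy(dtype=float)
    events = data[event_col].to_numpy(dtype=bool)
    labels = (data[group_col].astype(str).to_numpy() if group_col
              else np.repeat("all", len(data)))

    grid = np.arange(0, int(np.ceil(durations.max())) + 1)
    rows = []
    for g in pd.unique(labels):
        m = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(durations[m], events[m])
        surv = kmf.survival_function_at_times(grid).to_numpy()
        at_risk = (durations[m][None, :] >= grid[:, None]).sum(axis=1)
        rows.append(pd.DataFrame({"group": g, "month": grid,
                                  "at_risk": at_risk, "survival": surv}))
    table = pd.concat(rows, ignore_index=True)

    logrank_stat = logrank_p = None
    if events.sum() == 0:
        warnings.warn("no events: log-rank test undefined", UserWarning,
                      stacklevel=2)
    elif len(pd.unique(labels)) >= 2:
        res = multivariate_logrank_test(durations, labels, events)
        logrank_stat, logrank_p = float(res.test_statistic), float(res.p_value)
    return KMResult(table=table, logrank_stat=logrank_stat,
                    logrank_p=logrank_p)


def standardize_ls(values) -> np.ndarray:
    """z-standardize a score over the analysis sample (mean 0, SD 1).

    One unit of the result is one sample SD; for the Lifestyle Score that
    means one SD less healthy.  Zero variance is an error.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need >= 2 values to standardize")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: cannot standardize")
    return (arr - finite.mean()) / sd


def age_group(age) -> pd.Categorical:
    """Age strata <60, 60-69, >=70 (boundaries closed on the left)."""
    arr = np.asarray(age, dtype=float)
    idx = np.digitize(arr, [60.0, 70.0])  # right-open bins
    out = np.array(AGE_GROUP_LABELS, dtype=object)[idx]
    out = np.where(np.isfinite(arr), out, None)
    return pd.Categorical(out, categories=list(AGE_GROUP_LABELS), ordered=True)


@dataclass
class AgeInteractionResult:
    """Effect modification of the LS-mortality association by age group."""

    lrt_stat: float
    lrt_df: int
    lrt_p: float
    full_fit: CoxFit = field(repr=False)
    reduced_fit: CoxFit = field(repr=False)
    stratum_fits: dict = field(repr=False)     # age-group label -> CoxFit|None
    stratum_hr: pd.DataFrame = None            # HR per 1-SD LS_z per stratum
    elderly_tercile_fit: CoxFit | None = field(default=None, repr=False)
    elderly_tercile_hr: pd.DataFrame | None = None  # T2/T3 vs T1 in >=70


def _lrt(full: CoxFit, reduced: CoxFit, df: int):
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def _prepare_interaction_frame(df, ls_col, age_col, adjust, duration_col,
                               event_col, tercile_col=None):
    work = df.copy()
    if "male" in adjust and "male" not in work.columns:
        work["male"] = (work["sex"] == "male").astype(float)
    keep = [ls_col, age_col, duration_col, event_col, *adjust]
    if tercile_col and tercile_col in work.columns:
        keep.append(tercile_col)
    work = work[keep].dropna(subset=[ls_col, age_col, duration_col, event_col])
    work["ls_z"] = standardize_ls(work[ls_col])
    ag = age_group(work[age_col])
    work["ag2"] = (ag == AGE_GROUP_LABELS[1]).astype(float)
    work["ag3"] = (ag == AGE_GROUP_LABELS[2]).astype(float)
    work["ls_z_x_ag2"] = work["ls_z"] * work["ag2"]
    work["ls_z_x_ag3"] = work["ls_z"] * work["ag3"]
    work["_age_group"] = ag
    return work


def _interaction_terms(work: pd.DataFrame, adjust) -> tuple[list, list]:
    """Model terms, dropping dummies of age groups absent from the data."""
    base = ["ls_z", *adjust]
    inter = []
    for dummy, product in (("ag2", "ls_z_x_ag2"), ("ag3", "ls_z_x_ag3")):
        if work[dummy].nunique() > 1:
            base.append(dummy)
            inter.append(product)
    return base, inter


def interaction_lrt(df: pd.DataFrame, ls_col: str = "ls",
                    age_col: str = "age", adjust: tuple = ("male", "bmi"),
                    duration_col: str = "survival_months",
                    event_col: str = "event"):
    """Likelihood-ratio test for LS_z x age-group effect modification.

    Fits the nested Cox models with and without the two interaction terms
    and returns (statistic, df=2, p).
    """
    work = _prepare_interaction_frame(df, ls_col, age_col, adjust,
                                      duration_col, event_col)
    base, inter = _interaction_terms(work, adjust)
    if not inter:
        raise ValueError("no populated age group beyond the reference: "
                         "interaction test undefined")
    full = cox_fit(work, base + inter, duration_col, event_col)
    reduced = cox_fit(work, base, duration_col, event_col)
    stat, p = _lrt(full, reduced, df=len(inter))
    return stat, len(inter), p, full, reduced


def age_interaction_analysis(
    df: pd.DataFrame,
    ls_col: str = "ls",
    age_col: str = "age",
    tercile_col: str = "ls_tercile",
    adjust: tuple = ("male", "bmi"),
    duration_col: str = "survival_months",
    event_col: str = "event",
) -> AgeInteractionResult:
    """LS_z x age-group effect-modification analysis.

    (a) Nested Cox models with and without the two multiplicative
    interaction terms (LS_z x 60-69, LS_z x >=70); LRT statistic
    ``2 * delta(partial log-likelihood)`` on 2 df.  (b) Per-stratum Cox
    fits (adjusted for sex and BMI) reporting the HR per 1-SD LS_z.
    (c) Within the >=70 stratum, tercile-coded HRs against T1 (healthiest).

    Strata without events are reported as None.  The frame must carry
    `bmi` and a male indicator is derived from `sex` if absent.
    """
    work = _prepare_interaction_frame(df, ls_col, age_col, adjust,
                                      duration_col, event_col, tercile_col)
    base, inter = _interaction_terms(work, adjust)
    if not inter:
        raise ValueError("no populated age group beyond the reference: "
                         "interaction test undefined")
    full = cox_fit(work, base + inter, duration_col, event_col)
    reduced = cox_fit(work, base, duration_col, event_col)
    lrt_stat, lrt_p = _lrt(full, reduced, df=len(inter))

    stratum_fits = {}
    hr_rows = []
    for label in AGE_GROUP_LABELS:
        sub = work[work["_age_group"] == label]
        if len(sub) == 0 or sub[event_col].sum() == 0:
            stratum_fits[label] = None
            hr_rows.append({"age_group": label, "n": len(sub),
                            "n_events": int(sub[event_col].sum()) if len(sub)
                            else 0, "hr": np.nan, "lower": np.nan,
                            "upper": np.nan, "p": np.nan})
            continue
        try:
            fit = cox_fit(sub, ["ls_z", *adjust], duration_col, event_col)
        except (ValueError, RuntimeError):
            fit = None
        stratum_fits[label] = fit
        if fit is None:
            hr_rows.append({"age_group": label, "n": len(sub),
                            "n_events": int(sub[event_col].sum()),
                            "hr": np.nan, "lower": np.nan, "upper": np.nan,
                            "p": np.nan})
            continue
        hr_rows.append({
            "age_group": label, "n": fit.n, "n_events": fit.n_events,
            "hr": float(fit.hazard_ratios["ls_z"]),
            "lower": float(fit.ci_lower["ls_z"]),
            "upper": float(fit.ci_upper["ls_z"]),
            "p": float(fit.p_values["ls_z"]),
        })
    stratum_hr = pd.DataFrame(hr_rows)

    elderly_fit = None
    elderly_hr = None
    if tercile_col in work.columns:
        elderly = work[(work["_age_group"] == AGE_GROUP_LABELS[2])
                       & work[tercile_col].notna()]
        if len(elderly) and elderly[event_col].sum() > 0 \
                and elderly[tercile_col].nunique() > 1:
            try:
                elderly_fit = cox_fit(
                    elderly, [tercile_col, *adjust], duration_col, event_col,
                    factors={tercile_col: "T1"})
            except (ValueError, RuntimeError):
                elderly_fit = None
            rows = []
            for lvl in ("T2", "T3") if elderly_fit is not None else ():
                key = f"{tercile_col}[{lvl}]"
                if key in elderly_fit.hazard_ratios.index:
                    rows.append({
                        "contrast": f"{lvl} vs T1",
                        "hr": float(elderly_fit.hazard_ratios[key]),
                        "lower": float(elderly_fit.ci_lower[key]),
                        "upper": float(elderly_fit.ci_upper[key]),
                        "p": float(elderly_fit.p_values[key]),
                    })
            elderly_hr = pd.DataFrame(rows)

    return AgeInteractionResult(
        lrt_stat=lrt_stat, lrt_df=len(inter), lrt_p=lrt_p,
        full_fit=full, reduced_fit=reduced,
        stratum_fits=stratum_fits, stratum_hr=stratum_hr,
        elderly_tercile_fit=elderly_fit, elderly_tercile_hr=elderly_hr)
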