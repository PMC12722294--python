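"""One-command replication pipeline: simulate/score/describe/survive/compare.

`run_pipeline` ties the stages together on synthetic or user-supplied data
and writes a reproducible bundle of CSV tables plus a manifest recording
the seed, configuration hash and library versions.  Identical configuration
and seed produce a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .descriptives import (chi_square_independence, cross_tabulate,
                           score_correlations)
from .io import frame_checksum, read_cohort_csv, write_cohort_csv
from .longitudinal import longitudinal_report
from .scores import score_cohort
from .simulate import SimulationConfig, config_to_dict, generate_cohort, summarize_cohort
from .survival import age_interaction_analysis, cox_fit, km_curves, schoenfeld_check

logger = logging.getLogger(__name__)

#: Table-5-style model grid: score -> (continuous column, tercile column)
SCORE_MODELS = {
    "ls": ("ls", "ls_tercile"),
    "conut": ("conut", "conut_group"),
    "pni": ("pni", "pni_group"),
    "nri": ("nri", "nri_group"),
}
#: reference level per grouping column (3rd tercile / high group)
REFERENCE_LEVELS = {"ls_tercile": "T3", "conut_group": "high",
                    "pni_group": "T3", "nri_group": "T3"}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    input_csv: str | None = None          # None -> simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    out_dir: str = "lscohort_out"
    sep: str = ","
    decimal: str = "."
    covariates: tuple = ("age", "male", "bmi")
    framingham_mode: str = "tc"


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "input_csv": config.input_csv,
        "simulation": config_to_dict(config.simulation),
        "seed": config.seed,
        "covariates": list(config.covariates),
        "framingham_mode": config.framingham_mode,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def survival_fit_table(scored: pd.DataFrame,
                       covariates=("age", "male", "bmi")) -> pd.DataFrame:
    """Continuous and tercile-coded Cox fits for each score.

    Mirrors the mortality-model layout: each score enters once as a
    continuous covariate and once as a tercile/risk-group factor with the
    3rd-tercile/high group as reference, all adjusted for the same
    covariate set.
    """
    work = scored.copy()
    if "male" in covariates and "male" not in work.columns:
        work["male"] = (work["sex"] == "male").astype(float)
    rows = []
    for score, (cont_col, terc_col) in SCORE_MODELS.items():
        try:
            fit = cox_fit(work, [cont_col, *covariates])
        except (ValueError, RuntimeError) as exc:
            logger.warning("continuous %s model failed: %s", score, exc)
            fit = None
        if fit is not None:
            rows.append({"score": score, "term": "continuous",
                         "hr": fit.hazard_ratios[cont_col],
                         "lower": fit.ci_lower[cont_col],
                         "upper": fit.ci_upper[cont_col],
                         "p": fit.p_values[cont_col],
                         "n": fit.n, "n_events": fit.n_events})
        ref = REFERENCE_LEVELS[terc_col]
        try:
            tfit = cox_fit(work, [terc_col, *covariates],
                           factors={terc_col: ref})
        except (ValueError, RuntimeError) as exc:
            logger.warning("tercile %s model failed: %s", score, exc)
            continue
        for key in tfit.hazard_ratios.index:
            if key.startswith(f"{terc_col}["):
                level = key[len(terc_col) + 1:-1]
                rows.append({"score": score, "term": f"{level} vs {ref}",
                             "hr": tfit.hazard_ratios[key],
                             "lower": tfit.ci_lower[key],
                             "upper": tfit.ci_upper[key],
                             "p": tfit.p_values[key],
                             "n": tfit.n, "n_events": tfit.n_events})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to `out_dir`.

    Returns a dict of the in-memory artifacts (scored frame, summaries,
    cross-tabs, correlation panel, survival tables, longitudinal report,
    manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_csv:
        table = read_cohort_csv(config.input_csv, sep=config.sep,
                                decimal=config.decimal)
        cohort = table.frame
    else:
        sim = config.simulation.with_updates(seed=config.seed)
        cohort = generate_cohort(sim).frame

    scored = score_cohort(cohort, framingham_mode=config.framingham_mode)
    write_cohort_csv(scored, out / "scored_cohort.csv")

    summary = summarize_cohort(scored, group="ls_tercile")
    summary.to_csv(out / "grouped_summary.csv", index=False)

    crosstabs = {}
    chi2_rows = []
    for other in ("conut_group", "pni_group", "nri_group"):
        ct = cross_tabulate(scored["ls_tercile"], scored[other],
                            row_name="ls_tercile", col_name=other)
        crosstabs[other] = ct
        ct.counts.to_csv(out / f"crosstab_ls_{other}_counts.csv")
        ct.row_pct.to_csv(out / f"crosstab_ls_{other}_rowpct.csv",
                          float_format="%.1f")
        stat, dof, p = chi_square_independence(ct)
        chi2_rows.append({"table": f"ls_tercile x {other}",
                          "chi2": stat, "df": dof, "p": p})
    pd.DataFrame(chi2_rows).to_csv(out / "chi_square_tests.csv", index=False)

    correlations = score_correlations(scored)
    correlations.to_csv(out / "score_correlations.csv", index=False)

    fits = survival_fit_table(scored, covariates=config.covariates)
    fits.to_csv(out / "cox_fits.csv", index=False)

    km = km_curves(scored, group_col="ls_tercile")
    km.table.to_csv(out / "km_ls_terciles.csv", index=False)

    interaction = age_interaction_analysis(scored)
    interaction.stratum_hr.to_csv(out / "age_stratum_hr.csv", index=False)
    if interaction.elderly_tercile_hr is not None:
        interaction.elderly_tercile_hr.to_csv(
            out / "elderly_tercile_hr.csv", index=False)
    sch_p, sch_global = schoenfeld_check(interaction.reduced_fit)
    diagnostics = {
        "interaction_lrt_stat": interaction.lrt_stat,
        "interaction_lrt_df": interaction.lrt_df,
        "interaction_lrt_p": interaction.lrt_p,
        "logrank_ls_p": km.logrank_p,
        "schoenfeld_global_p": sch_global,
        "schoenfeld_per_covariate_p":
            sch_p.to_dict() if sch_p is not None else None,
    }

    longi = longitudinal_report(scored)
    longi["summary"].to_csv(out / "longitudinal_summary.csv", index=False)
    longi["between"].to_csv(out / "longitudinal_between_terciles.csv",
                            index=False)

    import lifelines
    import numpy
    import scipy

    manifest = {
        "package": f"lscohort {__version__}",
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "scored_cohort_sha256": frame_checksum(scored),
        "n": int(len(scored)),
        "versions": {"numpy": numpy.__version__,
                     "pandas": pd.__version__,
                     "scipy": scipy.__version__,
                     "lifelines": lifelines.__version__},
        "diagnostics": diagnostics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return {"scored": scored, "summary": summary, "crosstabs": crosstabs,
            "correlations": correlations, "cox_fits": fits, "km": km,
            "interaction": interaction, "longitudinal": longi,
            "manifest": manifest}
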