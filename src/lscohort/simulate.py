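"""Seeded synthetic cohort generator.

Emulates the structure of a large German population cohort (ages 18-80,
slight female majority) at the level the downstream analyses need: marginal
distributions of demographics and labs, an HDL-decreasing / triglyceride-
increasing gradient across Lifestyle Score terciles, a proportional-hazards
mortality process with administrative censoring, and an optional paired
lipid follow-up wave.  Every draw flows from a single integer seed, so a
given :class:`SimulationConfig` reproduces byte-identical cohorts.

Covariate correlation is induced by a small set of structural regressions
(weight on height and sex, lifestyle-dependent lab gradients, a shared
latent factor behind the four lifestyle sub-scores) rather than a full
copula: only the analysis-relevant dependence needs to hold.

Death times come from inverse-transform sampling of the cumulative hazard
``H(t) = lambda0 * t^k * exp(beta'x)`` (k = 1, i.e. exponential, by
default), censored administratively at the follow-up window.  The
log-hazard coefficient map supports score-derived covariates (``conut``,
``ls_z``, tercile indicators) and age-group interactions written as
products, e.g. ``"ls_t3:age70p"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .schemes import LS_SCHEME
from .scores import score_cohort

__all__ = ["LabSpec", "SubscoreSpec", "SimulationConfig", "SyntheticCohort",
           "generate_cohort", "summarize_cohort"]


@dataclass(frozen=True)
class LabSpec:
    mean: float
    sd: float
    family: str = "normal"  # or "lognormal"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class SubscoreSpec:
    """One lifestyle sub-score: integer points in [minimum, maximum]."""

    minimum: int
    maximum: int
    mean: float
    sd: float
    loading: float  # weight on the shared latent unhealthiness factor


def _default_subscores() -> dict:
    # Ranges chosen so the total spans 3-66; means/SDs and the shared-factor
    # loadings calibrated to a total of ~27.6 +/- 11.2 points.
    return {
        "diet": SubscoreSpec(1, 20, 8.9, 3.0, 2.8),
        "pa": SubscoreSpec(1, 16, 6.9, 3.0, 2.2),
        "smoking": SubscoreSpec(0, 15, 4.9, 3.0, 2.8),
        "alcohol": SubscoreSpec(1, 15, 6.5, 3.0, 2.2),
    }


def _default_labs() -> dict:
    return {
        "albumin": LabSpec(45.82, 2.45),            # g/L
        "total_cholesterol": LabSpec(5.58, 1.06),   # mmol/L
        "ldl": LabSpec(3.51, 0.96),                 # mmol/L
        "lymphocytes": LabSpec(1.88, 0.57, "lognormal"),  # 10^9/L
    }


@dataclass
class SimulationConfig:
    """All distributional and hazard parameters of the generator."""

    n: int = 6073
    seed: int = 0

    sex_fraction_female: float = 3147 / 6073
    age_mean: float = 55.48
    age_sd: float = 12.31
    age_min: float = 18.0
    age_max: float = 80.0

    height_mean: dict = field(
        default_factory=lambda: {"male": 176.87, "female": 163.86})
    height_sd: dict = field(
        default_factory=lambda: {"male": 7.28, "female": 6.87})
    weight_mean: dict = field(
        default_factory=lambda: {"male": 86.20, "female": 72.50})
    weight_sd: dict = field(
        default_factory=lambda: {"male": 14.62, "female": 14.57})
    weight_height_slope: float = 0.8  # kg per cm

    labs: dict = field(default_factory=_default_labs)
    #: per-tercile HDL means (mmol/L) and common SD: the decreasing gradient
    hdl_by_tercile: tuple = (1.72, 1.61, 1.52)
    hdl_sd: float = 0.46
    #: per-tercile triglyceride means (mmol/L, lognormal) - increasing
    tg_by_tercile: tuple = (1.24, 1.37, 1.56)
    tg_cv: float = 0.65

    subscores: dict = field(default_factory=_default_subscores)

    cvd_prevalence: float = 0.041

    baseline_hazard_family: str = "exponential"  # or "weibull"
    baseline_rate_per_month: float = 2.0e-4
    weibull_shape: float = 1.0
    log_hazard_coefficients: dict = field(
        default_factory=lambda: {"age_c": 0.09, "male": 0.40, "bmi_c": 0.02})
    followup_window_months: float = 110.0
    round_months: bool = True

    followup_fraction: float = 2530 / 6073
    #: mean baseline-minus-follow-up shift per LS tercile (storage sign
    #: convention: positive = decline over time)
    followup_shift: dict = field(default_factory=lambda: {
        "total_cholesterol": (0.22, 0.13, 0.14),
        "hdl": (0.11, 0.09, 0.10),
        "triglycerides": (-0.37, -0.45, -0.61),
    })
    followup_noise_sd: dict = field(default_factory=lambda: {
        "total_cholesterol": 1.00, "hdl": 0.42, "triglycerides": 0.90})

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.sex_fraction_female <= 1:
            raise ValueError("sex_fraction_female must be a proportion")
        if self.age_sd < 0 or self.age_min >= self.age_max:
            raise ValueError("infeasible age distribution")
        if self.baseline_rate_per_month <= 0 or self.weibull_shape <= 0:
            raise ValueError("hazard parameters must be positive")
        if self.baseline_hazard_family not in ("exponential", "weibull"):
            raise ValueError(
                f"unknown hazard family {self.baseline_hazard_family!r}")
        if self.followup_window_months <= 0:
            raise ValueError("followup window must be positive")
        if not 0 <= self.followup_fraction <= 1:
            raise ValueError("followup_fraction must be a proportion")
        for name, spec in self.labs.items():
            if spec.sd < 0:
                raise ValueError(f"negative sd for lab {name}")

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    """Generated records plus the generating truth for recovery tests."""

    frame: pd.DataFrame
    truth: SimulationConfig


def _lognormal(rng, mean, sd, size):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _tercile_index(ls: np.ndarray) -> np.ndarray:
    """0/1/2 for the fixed LS tercile cut-offs."""
    return np.digitize(ls, [LS_SCHEME.lower, LS_SCHEME.upper], right=True)


def resolve_covariate(name: str, df: pd.DataFrame) -> np.ndarray:
    """Resolve a log-hazard covariate name against a scored cohort frame.

    Atomic names: age, age_c, male, female, bmi, bmi_c, ls, ls_z, ls_t2,
    ls_t3, conut, pni, nri, diet_sub, pa_sub, smoking_sub, alcohol_sub,
    mace, diabetes, smoker, age_lt60, age60_69, age70p.  Products are
    written with ':' (e.g. ``ls_z:age70p``).
    """
    if ":" in name:
        parts = name.split(":")
        out = np.ones(len(df))
        for p in parts:
            out = out * resolve_covariate(p, df)
        return out
    age = df["age"].to_numpy(dtype=float)
    simple = {
        "age": lambda: age,
        "age_c": lambda: age - age.mean(),
        "male": lambda: (df["sex"] == "male").to_numpy(dtype=float),
        "female": lambda: (df["sex"] == "female").to_numpy(dtype=float),
        "bmi": lambda: df["bmi"].to_numpy(dtype=float),
        "bmi_c": lambda: df["bmi"].to_numpy(dtype=float)
        - np.nanmean(df["bmi"].to_numpy(dtype=float)),
        "ls": lambda: df["ls"].to_numpy(dtype=float),
        "ls_z": lambda: (
            (df["ls"] - df["ls"].mean()) / df["ls"].std(ddof=1)
        ).to_numpy(dtype=float),
        "ls_t2": lambda: (_tercile_index(df["ls"].to_numpy(dtype=float)) == 1)
        .astype(float),
        "ls_t3": lambda: (_tercile_index(df["ls"].to_numpy(dtype=float)) == 2)
        .astype(float),
        "conut": lambda: df["conut"].to_numpy(dtype=float),
        "pni": lambda: df["pni"].to_numpy(dtype=float),
        "nri": lambda: df["nri"].to_numpy(dtype=float),
        "diet_sub": lambda: df["diet_subscore"].to_numpy(dtype=float),
        "pa_sub": lambda: df["pa_subscore"].to_numpy(dtype=float),
        "smoking_sub": lambda: df["smoking_subscore"].to_numpy(dtype=float),
        "alcohol_sub": lambda: df["alcohol_subscore"].to_numpy(dtype=float),
        "mace": lambda: df["mace"].to_numpy(dtype=float),
        "diabetes": lambda: df["diabetes"].to_numpy(dtype=float),
        "smoker": lambda: df["smoker"].to_numpy(dtype=float),
        "age_lt60": lambda: (age < 60).astype(float),
        "age60_69": lambda: ((age >= 60) & (age < 70)).astype(float),
        "age70p": lambda: (age >= 70).astype(float),
    }
    if name not in simple:
        raise KeyError(f"unknown hazard covariate {name!r}")
    return simple[name]()


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort; `seed` overrides `config.seed` if given."""
    config = config or SimulationConfig()
    if seed is not None:
        config = config.with_updates(seed=int(seed))
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = np.where(rng.random(n) < config.sex_fraction_female,
                   "female", "male")
    a, b = ((config.age_min - config.age_mean) / config.age_sd,
            (config.age_max - config.age_mean) / config.age_sd)
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                        size=n, random_state=rng)

    height = np.empty(n)
    weight = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        height[m] = rng.normal(config.height_mean[s], config.height_sd[s],
                               m.sum())
        resid_var = max(
            config.weight_sd[s] ** 2
            - (config.weight_height_slope * config.height_sd[s]) ** 2,
            0.25 * config.weight_sd[s] ** 2,
        )
        weight[m] = (
            config.weight_mean[s]
            + config.weight_height_slope * (height[m] - config.height_mean[s])
            + rng.normal(0.0, np.sqrt(resid_var), m.sum())
        )
    weight = np.clip(weight, 35.0, None)

    # Lifestyle sub-scores share a latent unhealthiness factor.
    z = rng.normal(size=n)
    subs = {}
    for name, spec in config.subscores.items():
        raw = spec.mean + spec.loading * z + rng.normal(0.0, spec.sd, n)
        subs[name] = np.clip(np.round(raw), spec.minimum, spec.maximum)
    ls = sum(subs.values())
    tercile = _tercile_index(ls)

    labs = {}
    for name, spec in config.labs.items():
        if spec.family == "lognormal":
            labs[name] = _lognormal(rng, spec.mean, spec.sd, n)
        else:
            labs[name] = np.clip(rng.normal(spec.mean, spec.sd, n), 0.05, None)
    hdl = np.clip(
        np.asarray(config.hdl_by_tercile)[tercile]
        + rng.normal(0.0, config.hdl_sd, n),
        0.3, None,
    )
    tg_mean = np.asarray(config.tg_by_tercile)[tercile]
    tg = _lognormal(rng, 1.0, config.tg_cv, n) * tg_mean

    sbp = np.clip(110.0 + 0.33 * age + rng.normal(0.0, 14.0, n), 85.0, 230.0)
    dbp = np.clip(42.0 + 0.30 * sbp + rng.normal(0.0, 7.0, n), 50.0, 130.0)

    bmi = weight / (height / 100.0) ** 2
    diabetes = rng.random(n) < expit(
        -2.3 + 0.05 * (age - config.age_mean) + 0.07 * (bmi - 27.28))
    smoker = rng.random(n) < expit(-3.4 + 0.38 * subs["smoking"])
    alcohol_g = np.clip(
        np.exp(rng.normal(np.log(8.0) + 0.15 * (subs["alcohol"] - 6.6), 0.7))
        * np.where(sex == "female", 0.6, 1.0),
        0.0, 250.0,
    )
    mace = rng.random(n) < config.cvd_prevalence

    frame = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "height": height,
        "weight": weight,
        "albumin": labs["albumin"],
        "total_cholesterol": labs["total_cholesterol"],
        "hdl": hdl,
        "ldl": labs["ldl"],
        "triglycerides": tg,
        "lymphocytes": labs["lymphocytes"],
        "systolic_bp": sbp,
        "diastolic_bp": dbp,
        "diabetes": diabetes,
        "smoker": smoker,
        "diet_subscore": subs["diet"],
        "pa_subscore": subs["pa"],
        "smoking_subscore": subs["smoking"],
        "alcohol_g_per_day": alcohol_g,
        "alcohol_subscore": subs["alcohol"],
        "mace": mace,
    })

    # Mortality: linear predictor on the scored frame, inverse-transform
    # death times from the cumulative hazard, administrative censoring.
    scored = score_cohort(frame)
    lp = np.zeros(n)
    for name, beta in config.log_hazard_coefficients.items():
        lp += float(beta) * resolve_covariate(name, scored)
    shape = (1.0 if config.baseline_hazard_family == "exponential"
             else config.weibull_shape)
    u = rng.random(n)
    t_death = (-np.log(u) / (config.baseline_rate_per_month * np.exp(lp))) \
        ** (1.0 / shape)
    window = config.followup_window_months
    event = t_death <= window
    time = np.minimum(t_death, window)
    if config.round_months:
        time = np.where(event, np.maximum(np.ceil(time), 1.0), time)
    frame["survival_months"] = time
    frame["event"] = event

    # Paired follow-up lipids on a simple random subsample.
    n_fu = int(round(config.followup_fraction * n))
    fu_idx = rng.choice(n, size=n_fu, replace=False)
    in_fu = np.zeros(n, dtype=bool)
    in_fu[fu_idx] = True
    base_cols = {"total_cholesterol": labs["total_cholesterol"],
                 "hdl": hdl, "triglycerides": tg}
    for var, shifts in config.followup_shift.items():
        fu = (base_cols[var]
              - np.asarray(shifts)[tercile]
              + rng.normal(0.0, config.followup_noise_sd[var], n))
        fu = np.clip(fu, 0.05, None)
        frame[f"{var}_fu"] = np.where(in_fu, fu, np.nan)

    return SyntheticCohort(frame=frame, truth=config)


def summarize_cohort(cohort, group: str | None = None) -> pd.DataFrame:
    """Per-group n and mean/SD of every numeric variable (long format).

    `cohort` may be a :class:`SyntheticCohort` or a DataFrame (scored or
    raw).  Empty groups are reported with n = 0 and null statistics.
    """
    df = cohort.frame if isinstance(cohort, SyntheticCohort) else cohort
    if len(df) == 0:
        raise ValueError("empty cohort")
    num = df.select_dtypes(include=[np.number])
    rows = []
    if group is None:
        groups = [("all", df.index)]
    else:
        grouped = df.groupby(group, observed=False)
        groups = [(str(k), idx) for k, idx in grouped.groups.items()]
    for label, idx in groups:
        sub = num.loc[idx]
        for col in num.columns:
            vals = sub[col].dropna()
            rows.append({
                "variable": col,
                "group": label,
                "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable dump of the generating truth."""
    return asdict(config)
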