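# Methods

## Scores and unit contracts

All raw data are stored in one set of units (albumin g/L, cholesterol
fractions mmol/L, lymphocytes 10⁹/L, height cm, weight kg, survival time
months); every score that is defined on other units converts internally
through `lscohort.units`, with a single mmol/L→mg/dL factor of 38.67 for
cholesterol. A plausibility gate warns when albumin arrives in g/dL
magnitude (median outside 20–60), the most common unit mix-up for that
analyte.

**Lifestyle Score.** The LS is the plain sum of four questionnaire
sub-scores (diet, physical activity, smoking, alcohol; lower = healthier).
The questionnaire item scoring itself is out of scope — sub-scores are
pipeline inputs. The default sub-score schema used by the simulator (diet
1–20, physical activity 1–16, smoking 0–15, alcohol 1–15) is chosen so the
total spans 3–66. The fixed tercile scheme (≤21 / 22–32 / >32) places both
cut points in the lower category. Alcohol intake above 10 g/day (women) or
20 g/day (men) — the German Nutrition Society thresholds — is classified
as penalized; intake exactly at the threshold is not.

**CONUT.** Band point values are configuration data
(`data/score_bands.yaml`): albumin ≥35→0, 30–34.9→2, 25–29.9→4, <25→6;
cholesterol ≥4.65→0, 3.62–4.64→1, 2.59–3.61→2, <2.59→3 (mmol/L);
lymphocytes ≥1.6→0, 1.2–1.59→1, 0.8–1.19→2, <0.8→3 (10⁹/L). Band edges
are closed below. Risk groups: 0 low, 1–2 moderate, ≥3 high (the ≥3
convention is used for the high-risk boundary).

**PNI.** `10·albumin[g/dL] + 0.005·lymphocytes[mm⁻³]`. The formula is
stated in the literature sometimes with g/L, sometimes g/dL albumin; only
the g/dL version is dimensionally consistent with the published cohort
means (≈55 points at albumin 45.8 g/L), so the calculator converts to
g/dL. Terciles: >56.35 low risk (T1), 53.25–56.35 moderate, <53.25 high;
exact boundary values fall in the moderate band.

**NRI.** `1.489·albumin[g/L] + 41.7·(weight/ideal weight)` with the
Lorenz ideal weight (men: (h−100)−(h−150)/4; women: (h−100)−(h−150)/2.5).
The classic index caps the weight ratio at 1; with an ideal-weight
denominator the cap would truncate most of a well-nourished population,
so the ratio is deliberately left uncapped. Heights below 150 cm are
outside the Lorenz formula's intended regime: the arithmetic is returned
with a warning. Terciles: >122.8 / 115.2–122.8 / <115.2, boundaries in
the moderate band.

**Framingham risk.** The 1998 sex-specific categorical point tables
(age band, total- or LDL-cholesterol band, HDL band, JNC blood-pressure
category using the worse of SBP/DBP, diabetes, smoking) are shipped as
YAML data; the point total maps to a tabulated 10-year CHD risk percent.
TC scoring is the default, LDL selectable. The tables cover ages 30–74;
younger/older participants are clamped to the nearest band, and point
totals outside the tabulated range saturate at the extreme rows — both
standard calculator conventions. Risk categories follow the Sehestedt
bands: <5 low, [5,10) low-moderate, [10,20] moderate-high, >20 high.

Missingness is handled per score: a missing lab nulls only the scores
that need it, so each analysis uses its own complete-case subset.

## Synthetic cohort generator

The generator emulates the structure of a large German adult cohort
(n = 6,073 by default; 51.8 % women; truncated-normal age 55.5 ± 12.3 on
18–80) at the level the analyses need, with all randomness flowing from
one integer seed:

* height/weight: sex-specific normals with weight regressed on height
  (0.8 kg/cm), residual variance chosen to preserve the marginal SDs;
* labs: albumin 45.8 ± 2.45 g/L, total cholesterol 5.58 ± 1.06 and LDL
  3.51 ± 0.96 mmol/L (normal), lymphocytes 1.88 ± 0.57 10⁹/L and
  triglycerides (lognormal);
* the analysis-relevant gradients are imposed structurally: HDL means
  1.72/1.61/1.52 mmol/L and triglyceride means 1.24/1.37/1.56 mmol/L
  across LS terciles;
* lifestyle sub-scores are drawn around a shared latent "unhealthiness"
  factor (loadings 2.8/2.2/2.8/2.2, residual SD 3, rounded and clipped to
  their ranges), calibrated to the published LS mean 27.59 and SD 11.19;
  smoking status and alcohol grams/day are generated consistently with
  their sub-scores;
* mortality: death times by inverse-transform sampling from
  `H(t) = λ₀·t^k·exp(βᵀx)` (k = 1, exponential, by default; Weibull shape
  configurable), administrative censoring at 110 months, times rounded up
  to whole months to mimic registry date granularity (hence tied event
  times and the Efron correction downstream). The default baseline rate
  λ₀ = 2×10⁻⁴/month together with age (β = 0.09/yr, centered), male sex
  (β = 0.40) and BMI (β = 0.02) effects yields ≈4 % deaths in the window,
  the healthy-cohort regime of the motivating study. The coefficient map
  accepts score-derived covariates (`conut`, `ls_z`, tercile indicators)
  and age-group products such as `ls_t3:age70p`, which is how
  effect-modification scenarios are generated;
* a simple random subsample (fraction 2530/6073) receives follow-up
  lipids: `follow-up = baseline − shift(tercile) + noise`, with shifts
  matching the published sign pattern (cholesterol and HDL decline,
  triglycerides rise, most in tercile 3).

Covariate correlation is induced only through these structural
regressions, not a full copula: the package's tests need the
analysis-relevant dependence (gradients, hazards), not a complete joint
distribution. What the generator deliberately does *not* emulate:
recruitment stratification and non-response, medication effects on labs,
measurement error correlated over time, competing risks, or real
covariance between LS and age/labs beyond the configured gradients.
Passing recovery tests therefore demonstrate that the *estimators* are
correct under the assumed data-generating process, not that the published
effect estimates are unconfounded in real data.

## Statistical procedures

* **ANCOVA / Tukey.** Group comparisons adjust for covariates by OLS with
  the group coded as a factor; the group F-test is a type-II ANOVA. Tukey
  HSD is applied to covariate-adjusted (marginal) means via pairwise
  contrasts, with p-values from the studentized-range distribution —
  `pairwise_tukeyhsd` on raw data cannot adjust for covariates, hence the
  explicit contrast construction.
* **Rank tests.** Kruskal–Wallis for ≥3 groups, Wilcoxon rank-sum for 2;
  constant outcomes return p = 1 with a warning.
* **Chi-square.** Pearson, no continuity correction; a warning is raised
  when any expected count is below 5.
* **Correlations.** Spearman and Pearson for LS (and its smoking-excluded
  variant and sub-scores) against Framingham risk; Kendall's τ between the
  discrete diet/smoking sub-scores and the malnutrition indices, where
  heavy ties make τ the appropriate choice.
* **Empirical terciles** use order-statistic (type-1) quantiles so cuts
  land on observed values and boundary scores join the lower tercile,
  matching the fixed-scheme convention.
* **Cox models** delegate the partial-likelihood maximization to
  lifelines (Efron ties). Newton–Raphson at the library's default step
  size can overshoot on dummy-heavy designs, so fits run at step 0.5 with
  tightened precision (1e-10) and walk the step down (0.25, 0.1, 0.05)
  until genuine convergence; anything less raises. Factor covariates are
  dummy-coded against a declared reference — tercile models use the
  3rd-tercile/high group as reference so healthier groups get protective
  HRs; the ≥70-stratum tercile model uses T1 as reference to express risk
  gradients. Default adjustment set: age, sex, BMI (configurable; MACE
  optional).
* **Effect modification.** LS is z-standardized over the analysis sample
  (sample SD, ddof = 1); age groups <60 / 60–69 / ≥70 are closed on the
  left. The pooled model contains LS_z, age-group dummies, the adjustment
  set and the two LS_z×age-group products; the LRT is
  2·Δ(partial log-likelihood) on 2 df (df shrinks if an age group is
  empty, in which case its dummy and product are dropped and the stratum
  is reported null). Stratum fits adjust for sex and BMI only.
* **Schoenfeld diagnostics.** Per-covariate scaled-Schoenfeld tests
  (rank time transform) come from lifelines; the global value combines
  them by a Šidák correction on the minimum p. This is an approximation
  to the joint chi-square global test and is conservative under positive
  dependence; per-covariate p-values are always reported alongside.
* **Paired analysis.** Differences are `baseline − follow-up` (positive =
  decline). Per-participant differences drive the statistics; the
  reported `SD_diff ≈ √(SD²_base + SD²_follow)` independence
  approximation is computed exactly as printed sources use it (it
  overstates the true paired SD under positive wave correlation, so the
  exact paired SD is reported next to it). Wilcoxon signed-rank uses
  Pratt's zero handling, exact null for n < 25 without zeros/ties, normal
  approximation with tie correction otherwise.
* α = 0.05 two-sided throughout; raw p-values, no multiplicity
  correction — the analysis policy of the replicated design.

## Problem sizes and numerical choices

Simulation-backed tests use the smallest sizes at which the checked
property is stable: full-size cohorts (n = 6,073) only where the claim is
about the default study conditions, n ≈ 900–1,500 with an elevated
baseline hazard for calibration suites (null CI coverage at 50
replicates, type-I error of the interaction LRT at 400 replicates), and
5–6-person toys for the hand-checkable oracles (product-limit estimates,
brute-force 1-D partial-likelihood maximization, agreement to 1e-6).
Hazard-ratio recovery uses 50 replicates at full size and compares the
median estimate with the generating truth; the ≥70-stratum tercile
contrast sits in a genuinely wide-CI regime (~600 participants, ~130
events per replicate), so its recovery is assessed at a wider band than
the cohort-level CONUT effect.

## Known limitations

* The Framingham implementation is one specific published coefficient
  set; cohort-level means shift by ±1–2 risk points across calculator
  variants, which is why the simulator's cohort mean is checked only
  loosely against the reported value.
* The global Schoenfeld p is a conservative combination, not the joint
  statistic R's `cox.zph` prints.
* The generator's lab distributions are independent of age given the LS
  tercile; stratum-specific fits omitting age therefore see (small)
  non-collapsibility attenuation rather than real confounding.
* German-locale CSV support covers decimal commas and semicolon
  separators, not thousands separators.
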