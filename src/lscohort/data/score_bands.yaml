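# Band tables and tercile cut-offs for the clinical scores.
# version: 1
#
# CONUT bands follow the canonical published scheme (Ignacio de Ulibarri 2005):
# each analyte contributes points by band; the three contributions sum to 0-12.
# Band lists are [lower_edge, points] with ascending lower edges; a value scores
# the points of the highest band whose lower edge it reaches (edges are closed
# below: albumin 30 g/L scores 2, 35 g/L scores 0).
version: 1

conut:
  albumin_g_per_l:        # g/L
    - [.nan, 6]           # < 25
    - [25.0, 4]           # 25-29.9
    - [30.0, 2]           # 30-34.9
    - [35.0, 0]           # >= 35
  total_cholesterol_mmol_per_l:
    - [.nan, 3]           # < 2.59
    - [2.59, 2]           # 2.59-3.61
    - [3.62, 1]           # 3.62-4.64
    - [4.65, 0]           # >= 4.65
  lymphocytes_1e9_per_l:
    - [.nan, 3]           # < 0.8
    - [0.80, 2]           # 0.8-1.19
    - [1.20, 1]           # 1.2-1.59
    - [1.60, 0]           # >= 1.6

conut_groups:             # risk grouping of the 0-12 total
  low_max: 0              # 0 -> low
  moderate_max: 2         # 1-2 -> moderate; >= 3 -> high

tercile_schemes:
  ls:                     # higher score = less healthy lifestyle
    lower: 21.0           # T1: <= 21
    upper: 32.0           # T2: 22-32; T3: > 32
    direction: higher_is_worse
  pni:                    # lower score = higher malnutrition risk
    lower: 53.25          # T3: < 53.25
    upper: 56.35          # T2: 53.25-56.35 (closed); T1: > 56.35
    direction: lower_is_worse
  nri:
    lower: 115.2
    upper: 122.8
    direction: lower_is_worse

framingham_categories:    # Sehestedt 10-year CHD risk bands, percent
  low_max: 5.0            # < 5 -> low
  low_moderate_max: 10.0  # [5, 10) -> low_moderate
  moderate_high_max: 20.0 # [10, 20] -> moderate_high; > 20 -> high

alcohol_thresholds_g_per_day:
  female: 10.0
  male: 20.0
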