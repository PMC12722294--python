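# Framingham 10-year CHD risk: categorical point tables (Wilson et al. 1998).
# Two variants: total-cholesterol (tc) and LDL-cholesterol (ldl) scoring.
# Band lists are [lower_edge_mg_per_dl_or_years, points]; a value scores the
# points of the highest band whose lower edge it reaches. Blood pressure is
# scored by JNC category (optimal / normal / high-normal / stage 1 / stage 2),
# using the worse of the systolic and diastolic categories.
# `risk` maps total points -> 10-year CHD risk in percent; totals outside the
# listed range are clamped to the nearest listed row.
version: 1

bp_sbp_edges: [120, 130, 140, 160]   # category index 0..4
bp_dbp_edges: [80, 85, 90, 100]

tc:
  male:
    age:
      [[30, -1], [35, 0], [40, 1], [45, 2], [50, 3], [55, 4], [60, 5], [65, 6], [70, 7]]
    cholesterol:
      [[0, -3], [160, 0], [200, 1], [240, 2], [280, 3]]
    hdl:
      [[0, 2], [35, 1], [45, 0], [50, 0], [60, -2]]
    bp_points: [0, 0, 1, 2, 3]
    diabetes: 2
    smoker: 2
    risk:
      {-3: 1, -2: 2, -1: 2, 0: 3, 1: 3, 2: 4, 3: 5, 4: 7, 5: 8, 6: 10, 7: 13,
       8: 16, 9: 20, 10: 25, 11: 31, 12: 37, 13: 45, 14: 53}
  female:
    age:
      [[30, -9], [35, -4], [40, 0], [45, 3], [50, 6], [55, 7], [60, 8], [65, 8], [70, 8]]
    cholesterol:
      [[0, -2], [160, 0], [200, 1], [240, 2], [280, 3]]
    hdl:
      [[0, 5], [35, 2], [45, 1], [50, 0], [60, -3]]
    bp_points: [-3, 0, 0, 2, 3]
    diabetes: 4
    smoker: 2
    risk:
      {-2: 1, -1: 2, 0: 2, 1: 2, 2: 3, 3: 3, 4: 4, 5: 4, 6: 5, 7: 6, 8: 7,
       9: 8, 10: 10, 11: 11, 12: 13, 13: 15, 14: 18, 15: 20, 16: 24, 17: 27}

ldl:
  male:
    age:
      [[30, -1], [35, 0], [40, 1], [45, 2], [50, 3], [55, 4], [60, 5], [65, 6], [70, 7]]
    cholesterol:
      [[0, -3], [100, 0], [130, 0], [160, 1], [190, 2]]
    hdl:
      [[0, 2], [35, 1], [45, 0], [50, 0], [60, -1]]
    bp_points: [0, 0, 1, 2, 3]
    diabetes: 2
    smoker: 2
    risk:
      {-3: 1, -2: 2, -1: 2, 0: 3, 1: 4, 2: 4, 3: 6, 4: 7, 5: 9, 6: 11, 7: 14,
       8: 18, 9: 22, 10: 27, 11: 33, 12: 40, 13: 47, 14: 56}
  female:
    age:
      [[30, -9], [35, -4], [40, 0], [45, 3], [50, 6], [55, 7], [60, 8], [65, 8], [70, 8]]
    cholesterol:
      [[0, -2], [100, 0], [130, 0], [160, 2], [190, 2]]
    hdl:
      [[0, 5], [35, 2], [45, 1], [50, 0], [60, -2]]
    bp_points: [-3, 0, 0, 2, 3]
    diabetes: 4
    smoker: 2
    risk:
      {-2: 1, -1: 2, 0: 2, 1: 2, 2: 3, 3: 3, 4: 4, 5: 5, 6: 6, 7: 7, 8: 8,
       9: 9, 10: 11, 11: 13, 12: 15, 13: 17, 14: 20, 15: 24, 16: 27, 17: 32}
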