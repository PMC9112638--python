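# Default surveillance rule set, hand-transcribed from the Canadian Association
# of Gastroenterology recommendations, with the US Multi-Society Task Force
# tables filling the gaps CAG does not address (post-CRC-resection follow-up,
# second-surveillance grid).  Intervals are closed ranges in MONTHS.
#
# Predicate semantics (all clauses AND-ed; bounds closed; null = unbounded):
#   no_polyps          : true  -> matches only a normal exam
#   adenoma_count      : [lo, hi]  total count over tubular / tubulovillous-villous / HGD groups
#   adenoma_max_size   : [lo, hi]  largest adenoma, mm (0 groups -> no match when lo >= 1)
#   serrated_count     : [lo, hi]  total count over SSP / SSP-with-dysplasia groups
#   serrated_max_size  : [lo, hi]  largest sessile serrated lesion, mm
#   histology_present  : histology name that must appear in the findings
#   hp_max_size        : [lo, hi]  largest hyperplastic polyp, mm
#   hp_location        : RECTOSIGMOID -> every HP group is rectosigmoid;
#                        PROXIMAL     -> at least one HP group proximal or unknown
#   piecemeal_max_size : [lo, hi]  largest lesion removed piecemeal, mm

version: "1"
id: cag-usmstf-default

index_rules:
  - id: no_polyps
    when: {no_polyps: true}
    months: [120, 120]
  - id: ta_1_2_lt10
    when: {adenoma_count: [1, 2], adenoma_max_size: [1, 9]}
    months: [84, 120]
  - id: ta_3_4_lt10
    when: {adenoma_count: [3, 4], adenoma_max_size: [1, 9]}
    months: [36, 60]
  - id: adenoma_5_10
    when: {adenoma_count: [5, 10]}
    months: [36, 36]
  - id: adenoma_ge10mm
    when: {adenoma_max_size: [10, null]}
    months: [36, 36]
  - id: villous_any
    when: {histology_present: TUBULOVILLOUS_OR_VILLOUS}
    months: [36, 36]
  - id: hgd_any
    when: {histology_present: ADENOMA_HGD}
    months: [36, 36]
  - id: adenoma_gt10
    when: {adenoma_count: [11, null]}
    months: [12, 12]
  - id: ssp_1_2_lt10
    when: {serrated_count: [1, 2], serrated_max_size: [1, 9]}
    months: [60, 120]
  - id: ssp_3_4_lt10
    when: {serrated_count: [3, 4], serrated_max_size: [1, 9]}
    months: [36, 60]
  - id: ssp_5_10
    when: {serrated_count: [5, null]}
    months: [36, 36]
  - id: ssp_ge10mm
    when: {serrated_max_size: [10, null]}
    months: [36, 36]
  - id: ssp_dysplasia
    when: {histology_present: SSP_DYSPLASIA}
    months: [36, 36]
  - id: tsa_any
    when: {histology_present: TSA}
    months: [36, 36]
  - id: hp_ge10mm
    when: {hp_max_size: [10, null]}
    months: [36, 60]
  - id: hp_rectosigmoid_lt10
    when: {hp_max_size: [1, 9], hp_location: RECTOSIGMOID}
    months: [120, 120]
  - id: hp_proximal_lt10
    when: {hp_max_size: [1, 9], hp_location: PROXIMAL}
    months: [60, 120]
  - id: piecemeal_ge20mm
    when: {piecemeal_max_size: [20, null]}
    months: [6, 6]

# Second-surveillance grid: interval keyed by (risk class of the PRIOR exam,
# risk class of the CURRENT exam).  When the current exam is not normal the
# engine additionally runs the index rules on it and keeps the shorter result.
surveillance_step:
  NORMAL:
    NORMAL: [120, 120]
    LOW_RISK: [84, 120]
    HIGH_RISK: [36, 36]
  LOW_RISK:
    NORMAL: [120, 120]
    LOW_RISK: [60, 60]
    HIGH_RISK: [36, 36]
  HIGH_RISK:
    NORMAL: [60, 60]
    LOW_RISK: [60, 60]
    HIGH_RISK: [36, 36]

# Follow-up after colorectal-cancer resection, keyed by how many surveillance
# colonoscopies have already been done since the resection (last entry applies
# to that count or more).
post_crc_sequence:
  - count: 0
    months: [12, 12]
  - count: 1
    months: [36, 36]
  - count: 2
    months: [60, 60]

# Family-history modifier: caps (elementwise min) applied to an interval result.
family_history_rules:
  high_risk_cap_months: 60     # >= 2 FDRs with CRC, or any FDR dx < 60, or FDR advanced adenoma dx < 60
  average_elevated_cap_months: 120   # single FDR (CRC or advanced adenoma) diagnosed at >= 60

options:
  # High-risk definition used by the second-surveillance risk classifier.
  high_risk:
    adenoma_min_size_mm: 10
    adenoma_min_count: 5
    serrated_min_size_mm: 10
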