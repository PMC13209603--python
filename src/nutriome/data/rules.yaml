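# Demonstration subcategory rule file for the risk-label engine.
#
# score = sum(weight * risk-allele dosage) / sum(2 * weight) over the
# informative variants of a subcategory, so 0 means no risk allele seen
# and 1 means homozygous risk at every variant.  Thresholds map the score
# to the label set; a subcategory with a missing-call fraction above
# max_missing_fraction is reported non-informative.
version: demo-1
defaults:
  label_set: risk-graded
  # 4 breakpoints -> no/low/medium/moderate/high risk
  score_thresholds: [0.125, 0.375, 0.625, 0.875]
  max_missing_fraction: 0.34
rules:
  - {subcategory: lactose_intolerance}
  - {subcategory: gluten_sensitivity}
  - {subcategory: dao_intolerance}
  - {subcategory: vitamin_d_deficiency}
  - {subcategory: mthfr_deficiency}
  - {subcategory: iron_overload}
  - {subcategory: overweight}
  - {subcategory: ldl_levels}
  - {subcategory: triglyceride_response,
     label_set: valence, score_thresholds: [0.34, 0.67]}
  - {subcategory: saturated_fat_response,
     label_set: valence, score_thresholds: [0.34, 0.67]}
  - {subcategory: caffeine_metabolism,
     label_set: valence, score_thresholds: [0.34, 0.67]}
  - {subcategory: alcohol_flush}
  - {subcategory: power_performance,
     label_set: valence, score_thresholds: [0.34, 0.67]}
  - {subcategory: endurance_capacity,
     label_set: valence, score_thresholds: [0.34, 0.67]}
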