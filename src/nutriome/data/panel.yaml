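# Demonstration nutrigenetic panel (schematic).
#
# The production panel comprises 300 variants in 160 genes over 7
# categories and 39 subcategories; its variant list is not public.  This
# demo file shows the schema on a handful of well-known nutrition-related
# variants (rsIDs real, subcategory assignment and weights editorial) and
# is meant to be replaced by a curated configuration.  Use
# nutriome.nutrigenetics.demo_panel() for a synthetic full-size panel.
panel:
  - {variant_id: rs4988235, gene: MCM6, chrom: "2", pos: 135851076, ref: G, alt: A,
     risk_allele: G, category: Food intolerance, subcategory: lactose_intolerance}
  - {variant_id: rs182549, gene: MCM6, chrom: "2", pos: 135837906, ref: C, alt: T,
     risk_allele: C, category: Food intolerance, subcategory: lactose_intolerance}
  - {variant_id: rs2187668, gene: HLA-DQA1, chrom: "6", pos: 32713862, ref: C, alt: T,
     risk_allele: T, category: Food intolerance, subcategory: gluten_sensitivity}
  - {variant_id: rs7454108, gene: HLA-DQB1, chrom: "6", pos: 32698903, ref: T, alt: C,
     risk_allele: C, category: Food intolerance, subcategory: gluten_sensitivity}
  - {variant_id: rs10156191, gene: AOC1, chrom: "7", pos: 150860577, ref: C, alt: T,
     risk_allele: T, category: Food intolerance, subcategory: dao_intolerance}
  - {variant_id: rs1049793, gene: AOC1, chrom: "7", pos: 150865467, ref: C, alt: G,
     risk_allele: G, category: Food intolerance, subcategory: dao_intolerance}
  - {variant_id: rs2282679, gene: GC, chrom: "4", pos: 71742666, ref: T, alt: G,
     risk_allele: G, category: Vitamins and minerals, subcategory: vitamin_d_deficiency}
  - {variant_id: rs10741657, gene: CYP2R1, chrom: "11", pos: 14893332, ref: G, alt: A,
     risk_allele: G, category: Vitamins and minerals, subcategory: vitamin_d_deficiency}
  - {variant_id: rs1801133, gene: MTHFR, chrom: "1", pos: 11796321, ref: G, alt: A,
     risk_allele: A, category: Methylation profile, subcategory: mthfr_deficiency}
  - {variant_id: rs1801131, gene: MTHFR, chrom: "1", pos: 11794419, ref: T, alt: G,
     risk_allele: G, category: Methylation profile, subcategory: mthfr_deficiency}
  - {variant_id: rs1799945, gene: HFE, chrom: "6", pos: 26090951, ref: C, alt: G,
     risk_allele: G, category: Vitamins and minerals, subcategory: iron_overload}
  - {variant_id: rs1800562, gene: HFE, chrom: "6", pos: 26092913, ref: G, alt: A,
     risk_allele: A, category: Vitamins and minerals, subcategory: iron_overload}
  - {variant_id: rs9939609, gene: FTO, chrom: "16", pos: 53786615, ref: T, alt: A,
     risk_allele: A, category: Metabolic diseases, subcategory: overweight}
  - {variant_id: rs17782313, gene: MC4R, chrom: "18", pos: 60183864, ref: T, alt: C,
     risk_allele: C, category: Metabolic diseases, subcategory: overweight}
  - {variant_id: rs429358, gene: APOE, chrom: "19", pos: 44908684, ref: T, alt: C,
     risk_allele: C, category: Metabolic diseases, subcategory: ldl_levels}
  - {variant_id: rs646776, gene: SORT1, chrom: "1", pos: 109275908, ref: T, alt: C,
     risk_allele: T, category: Metabolic diseases, subcategory: ldl_levels}
  - {variant_id: rs1260326, gene: GCKR, chrom: "2", pos: 27508073, ref: C, alt: T,
     risk_allele: T, category: Response to diet, subcategory: triglyceride_response}
  - {variant_id: rs5082, gene: APOA2, chrom: "1", pos: 161222292, ref: A, alt: G,
     risk_allele: G, category: Response to diet, subcategory: saturated_fat_response}
  - {variant_id: rs762551, gene: CYP1A2, chrom: "15", pos: 74749576, ref: A, alt: C,
     risk_allele: C, category: Dietary habits, subcategory: caffeine_metabolism}
  - {variant_id: rs671, gene: ALDH2, chrom: "12", pos: 111803962, ref: G, alt: A,
     risk_allele: A, category: Dietary habits, subcategory: alcohol_flush}
  - {variant_id: rs1815739, gene: ACTN3, chrom: "11", pos: 66560624, ref: C, alt: T,
     risk_allele: T, category: Response to physical exercise, subcategory: power_performance}
  - {variant_id: rs8192678, gene: PPARGC1A, chrom: "4", pos: 23814039, ref: C, alt: T,
     risk_allele: T, category: Response to physical exercise, subcategory: endurance_capacity}
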