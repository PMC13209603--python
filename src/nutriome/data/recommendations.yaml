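# Recommendation texts attached to flagged results in the rendered report.
#
# Resolution order for a (key, label) pair: an explicit entry under
# `features:` or `genetics:`, then the per-label default template for its
# section.  A pair that resolves nowhere is a rendering error (no silent
# omission).  Texts are editorial demonstrations.
features:
  lipid:
    moderate: >-
      Lipid-degrading bacteria are somewhat elevated: moderate your
      overall fat intake and favor unsaturated sources.
    high: >-
      Lipid-degrading bacteria are in clear excess of the reference
      population: reduce overall fat intake and, preferably, replace
      animal fat with fish fat.
  methane:
    moderate: >-
      Methane-producing archaea are above reference levels; increase
      soluble fiber gradually and monitor bloating.
    high: >-
      Methane producers are strongly elevated, a pattern linked to slow
      transit; prioritize soluble fiber, hydration, and regular physical
      activity.
  pathogens:
    moderate: >-
      Potentially pathogenic genera are detectable above reference
      levels; favor fermented foods and discuss persistent symptoms with
      a clinician.
    high: >-
      Potentially pathogenic genera are strongly over-represented;
      medical follow-up is advised.
  protein:
    moderate: >-
      Protein-degrading (putrefactive) bacteria are elevated; rebalance
      toward plant proteins and increase fermentable fiber.
    high: >-
      Protein-degrading bacteria are in marked excess; reduce total
      protein load, especially red meat, and increase fiber.
  mucin:
    moderate: >-
      Mucin-degrading bacteria are elevated; support the mucus layer
      with polyphenol-rich foods and adequate fiber.
    high: >-
      Mucin degraders are strongly elevated, which may thin the gut
      mucus layer; avoid prolonged fasting and emphasize prebiotic fiber.
  lps:
    moderate: >-
      Lipopolysaccharide producers are elevated; limit saturated fat and
      alcohol, which promote endotoxin translocation.
    high: >-
      LPS producers are in marked excess; strongly limit saturated fat
      and alcohol and increase fiber diversity.
  butyrate:
    moderate: >-
      Butyrate producers are below reference; add resistant starch
      (cooled potatoes, legumes) and whole grains.
    high: >-
      Butyrate producers are strongly depleted; prioritize resistant
      starch, legumes, and a wider variety of plant fiber.
  diversity:
    moderate: >-
      Microbiome diversity is below the reference range; broaden the
      variety of plant foods across the week.
    high: >-
      Microbiome diversity is well below reference; aim for 30+ distinct
      plant foods weekly and limit ultra-processed items.
  phylum_ratio:
    moderate: >-
      The Bacillota-to-Bacteroidota balance deviates from reference;
      review fiber and fat intake balance.
    high: >-
      The Bacillota-to-Bacteroidota balance deviates strongly from
      reference; rebalance energy intake and fiber sources.
  # Labels for keys without an explicit entry fall through to these:
  default:
    moderate: >-
      This microbiome feature is moderately dysregulated relative to the
      reference population; targeted dietary adjustment is suggested.
    high: >-
      This microbiome feature is highly dysregulated relative to the
      reference population; a focused dietary intervention is suggested.
genetics:
  lactose_intolerance:
    "high risk": >-
      Genotype consistent with lactase non-persistence: prefer
      lactose-free dairy or hard cheeses and monitor symptoms.
  overweight:
    "high risk": >-
      Elevated polygenic predisposition to weight gain: emphasize energy
      balance, protein at breakfast, and regular activity.
  default:
    "no risk": No specific action needed for this trait.
    "low risk": Keep current habits; routine dietary variety is sufficient.
    "medium risk": >-
      Intermediate genetic predisposition: follow the general dietary
      guidance for this trait.
    "moderate risk": >-
      Raised genetic predisposition: adopt the targeted dietary guidance
      for this trait.
    "high risk": >-
      High genetic predisposition: prioritize the targeted dietary
      guidance for this trait and consider professional follow-up.
    favorable: Genotype favorable for this trait; no adjustment needed.
    neutral: Genotype neutral for this trait.
    unfavorable: >-
      Genotype unfavorable for this trait: follow the targeted dietary
      guidance.
    non-informative: >-
      Genotype calls were insufficient to score this trait; no
      recommendation is derived.
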