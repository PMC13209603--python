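# Conventional adult reference ranges for the blood-biomarker classifier.
# NON-AUTHORITATIVE: the study's analyte-specific ranges are not public;
# these are textbook values shipped so the classifier is runnable, and
# every report states the margin convention used.
borderline_margin: 0.1   # fraction of range width outside the range
analytes:
  glucose:            {unit: mg/dL, range_low: 70,  range_high: 100}
  total_cholesterol:  {unit: mg/dL, range_low: 125, range_high: 200}
  ldl_cholesterol:    {unit: mg/dL, range_low: 50,  range_high: 130}
  hdl_cholesterol:    {unit: mg/dL, range_low: 40,  range_high: 90}
  triglycerides:      {unit: mg/dL, range_low: 40,  range_high: 150}
  hemoglobin:         {unit: g/dL,  range_low: 12,  range_high: 17.5}
  iron:               {unit: ug/dL, range_low: 60,  range_high: 170}
  ferritin:           {unit: ng/mL, range_low: 20,  range_high: 250}
  vitamin_d:          {unit: ng/mL, range_low: 30,  range_high: 100}
  vitamin_b12:        {unit: pg/mL, range_low: 200, range_high: 900}
  folate:             {unit: ng/mL, range_low: 3,   range_high: 17}
  tsh:                {unit: mIU/L, range_low: 0.4, range_high: 4.0}
  creatinine:         {unit: mg/dL, range_low: 0.6, range_high: 1.3}
  alt:                {unit: U/L,   range_low: 7,   range_high: 56}
  crp:                {unit: mg/L,  range_low: 0,   range_high: 5}
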