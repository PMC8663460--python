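# Claims-derived rates and cost parameters for the national projection.
# Counts are the claims-population numerator/denominator pairs behind each
# rate; the national block holds the method-specific census-scale inputs.
claims_rates:
  nvaf_prevalence: 0.015290367  # 967,801 / 63,296,120
  eligible_fraction: 0.843396  # 816,240 / 967,801
  untreated_fraction: 0.607381  # 495,749 / 816,240
  stroke_risk: 0.0444
  stroke_death_risk: 0.0599
  counts:
    nvaf_prevalence: [967801, 63296120]
    eligible_fraction: [816240, 967801]
    untreated_fraction: [495749, 816240]
    stroke_risk: [22021, 495749]
    stroke_death_risk: [1320, 22021]
cost_params:
  pre_stroke_monthly: 2763.33
  post_stroke_monthly: 11538.0
  adjusted_monthly_savings: 8556.66
  bleed_rate: 0.0034
  bleed_cost: 23777.67
  therapy_cost_pmpm: 76.19
  inflation_rate: 0.019
  national_therapy_cost: 3750758790.0
  include_bleed_offset: false
national:
  population: 316005000
  structured_needing: 3009840
  combined_needing: 3976057
  nvaf_populations: [4955284, 6545930]
  eligible_populations: [4543995, 6002707]
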