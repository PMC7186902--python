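# Default synthetic community scenario: five species-like strata spanning the
# four-order-of-magnitude spread of foliar cyanogenesis, measured with the
# 5-min cup evacuation protocol at realistic meter noise.
strata:
  - {name: highly_cyanogenic, n: 8, per_gram_low: 2.0, per_gram_high: 15.0}
  - {name: moderately_cyanogenic, n: 8, per_gram_low: 0.5, per_gram_high: 5.0}
  - {name: variable, n: 8, per_gram_low: 0.1, per_gram_high: 10.0}
  - {name: low_variable, n: 8, per_gram_low: 0.01, per_gram_high: 1.0}
  - {name: acyanogenic, n: 4, per_gram_low: 0.0, per_gram_high: 0.0}
measurement:
  method: cup
  reading_interval_min: 5.0
  recovery_efficiency: 0.09803921568627451  # 1 / 10.2
  noise_cv: 0.05
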