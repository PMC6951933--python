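breed_name: Holstein
semen_type: sexed
birth_weight: 40.8
average_daily_gain: 0.9
mature_weight_cap: 680.0
female_prob_by_semen:
  sexed: 0.9
  conventional: 0.49
puberty_base_age: 400
first_ovulation_delay_mean: 19.0
first_ovulation_delay_sd: 11.0
cycle_length_mean: 21.0
cycle_length_sd: 4.0
heat_detection_prob: 0.6
conception_first_service: 0.339
conception_decrement_per_service: 0.026
conception_floor: 0.0
diagnosis_days:
- 32
- 91
- 200
daily_loss_rates:
- 0.0096
- 0.0017
gestation_mean: 278.0
gestation_sd: 6.0
heifer_cull_age: 650
cow_cull_dim: 300
culling_reason_probs:
  lameness: 0.04
  injury: 0.02
  mastitis: 0.07
  other_diseases: 0.05
  udder_problems: 0.03
  unknown: 0.04
culling_age_cdf:
  age_days:
  - 730
  - 1095
  - 1460
  - 1825
  - 2190
  - 2555
  - 2920
  - 3285
  - 3650
  cumulative_probability:
  - 0.05
  - 0.15
  - 0.33
  - 0.52
  - 0.68
  - 0.8
  - 0.89
  - 0.95
  - 1.0
lactation:
- breed: Holstein
  parity_class: '1'
  form: WOOD
  a: 16.5
  b: 0.22
  c: 0.0024
  d: 0.0
- breed: Holstein
  parity_class: '2'
  form: WOOD
  a: 21.0
  b: 0.24
  c: 0.003
  d: 0.0
- breed: Holstein
  parity_class: 3+
  form: WOOD
  a: 23.0
  b: 0.25
  c: 0.0033
  d: 0.0
dry_period_length: 60
seed: 12345
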