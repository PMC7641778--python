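# Demo pipeline config: small synthetic panel, fixed orders, modest bootstrap.
# Runs end-to-end in well under a minute and is byte-identical under the seed.
seed: 42
simulation:
  n_geographies: 12
  topics: [union, training, immunity, militarization]
  start: "2018-07-01"
  end: "2020-07-05"
  event_date: "2020-05-25"
  ar_coeffs: [0.5]
  ma_coeffs: []
  d: 0
  innovation_sd: 0.4
  mean_level: 8.0
  geo_level_sigma: 0.3
  effect_multiplier: 37.7
  decay_halflife: 10.0
  floor_multiplier: 5.0
  topic_intercepts: {union: 0.10, training: 0.55, immunity: 0.20, militarization: 0.15}
  topic_slopes: {union: 0.45, training: -0.43, immunity: 0.0, militarization: -0.02}
  vote_share_range: [0.25, 0.75]
model:
  orders: [1, 0, 0]
  drift: true
  level: 0.95
bootstrap:
  B: 400
geo:
  contrast_k: 3
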