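{
  "C10_kPa": 15.14,
  "C01": 13.48,
  "k1_MPa": 0.1526,
  "k2": 107.3,
  "theta_deg": 7.81,
  "beta_MPa": 5.84,
  "mean_fiber_deg": 45.0
}
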