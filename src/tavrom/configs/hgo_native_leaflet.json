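{
  "C10_kPa": 0.1463,
  "C01": 26.21,
  "k1_MPa": 0.007072,
  "k2": 147.5,
  "theta_deg": 26.21,
  "beta_MPa": 141.0,
  "mean_fiber_deg": 0.0
}
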