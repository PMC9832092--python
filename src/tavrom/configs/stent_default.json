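{
  "n_circumferential": 12,
  "n_rows": 5,
  "diameter_mm": 26.0,
  "height_mm": 45.0,
  "spring_k_dyne_cm": 100000.0,
  "beam_k_dyne_cm": 1000.0,
  "damping_dyne_s_cm": 10000.0,
  "crimp_stop_Fr": 17.25,
  "crimper_speed_cm_s": 50.0,
  "tether_stiffness_dyne_cm": 300000000.0
}
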