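{
  "Qvein_L_min": 5.8,
  "Rmv_mmHg_s_mL": 0.005,
  "Rlvot_mmHg_s_mL": 0.0043,
  "Rc_mmHg_s_mL": 0.042,
  "Rp_mmHg_s_mL": 0.9046,
  "C_mL_mmHg": 1.9504,
  "T_s": 0.8512,
  "elastance_LV": {
    "tau1_frac_T": 0.0725,
    "tau2_frac_T": 0.4503,
    "m1": 2.7463,
    "m2": 21.5683,
    "Emin_mmHg_mL": 0.01,
    "Emax_mmHg_mL": 0.1191
  },
  "elastance_LA": {
    "tau1_frac_T": 0.115,
    "tau2_frac_T": 0.1882,
    "m1": 1.32,
    "m2": 13.1,
    "Emin_mmHg_mL": 0.08,
    "Emax_mmHg_mL": 0.17
  },
  "la_shift_frac_T": 0.85,
  "la_shift_sign": "delay"
}
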