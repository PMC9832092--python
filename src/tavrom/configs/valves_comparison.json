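{
  "healthy": {"kind": "orifice", "EOA_cm2": 3.63},
  "stenotic": {"kind": "orifice", "EOA_cm2": 0.76},
  "tavr": {"kind": "orifice", "EOA_cm2": 1.32}
}
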