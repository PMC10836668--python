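{
  "model": "phenology",
  "mode": "start",
  "criterion": 2.5,
  "note": "Reference thermal-forcing parameters for the 2.5%-criterion start day (Islamabad, calibrated on 2004-2015).",
  "params": {"F1": "02-02", "d": -0.25, "c": 14.0},
  "M": 16.28
}
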