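{
  "model": "phenology",
  "mode": "peak",
  "criterion": 5,
  "note": "Reference degree-day parameters for the peak day under the 5% start criterion (Islamabad, calibrated on 2004-2015).",
  "params": {"T_D": 16.0, "Th": 11.0},
  "M": 34.08
}
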