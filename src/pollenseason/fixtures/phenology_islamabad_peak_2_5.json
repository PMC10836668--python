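{
  "model": "phenology",
  "mode": "peak",
  "criterion": 2.5,
  "note": "Reference degree-day parameters for the peak day under the 2.5% start criterion (Islamabad, calibrated on 2004-2015).",
  "params": {"T_D": 15.0, "Th": 12.0},
  "M": 39.07
}
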