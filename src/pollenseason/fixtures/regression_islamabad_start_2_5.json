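{
  "model": "linear",
  "response": "start_2_5",
  "note": "Reference coefficient set for the 2.5%-criterion start day of the spring paper-mulberry pollen season in Islamabad, fitted on 2004-2015 observations.",
  "window": {"start": "01-28", "end": "03-07"},
  "variables": ["T", "H", "Rf", "Sd", "Wd", "Wg"],
  "intercept": 137.151,
  "coefficients": {
    "T": -3.931,
    "H": -0.570,
    "Rf": 0.010,
    "Sd": -0.053,
    "Wd": 0.170,
    "Wg": 2.282
  }
}
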