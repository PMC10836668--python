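{
  "model": "linear",
  "response": "peak_2_5",
  "note": "Reference coefficient set for the peak day under the 2.5% start criterion (Islamabad, 2004-2015); the window closes at each year's season start and the start day itself is a predictor.",
  "window": {"start": "02-07", "end": "mps_start"},
  "variables": ["start_day", "T", "Rf", "Cc", "Sd", "Wd", "Wg"],
  "intercept": 97.853,
  "coefficients": {
    "start_day": 0.635,
    "T": -1.249,
    "Rf": -0.026,
    "Cc": -0.534,
    "Sd": -0.111,
    "Wd": 0.138,
    "Wg": 1.105
  }
}
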