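{
  "model": "linear",
  "response": "peak_5",
  "note": "Reference coefficient set for the peak day under the 5% start criterion (Islamabad, 2004-2015); the window closes at each year's season start and the start day itself is a predictor.",
  "window": {"start": "02-20", "end": "mps_start"},
  "variables": ["start_day", "T", "H", "Cc", "Sd", "Ws", "Wd", "Wg"],
  "intercept": 90.623,
  "coefficients": {
    "start_day": -0.301,
    "T": -1.183,
    "H": 0.016,
    "Cc": -0.187,
    "Sd": -0.031,
    "Ws": -1.039,
    "Wd": 0.371,
    "Wg": -0.126
  }
}
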