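{
  "model": "linear",
  "response": "start_5",
  "note": "Reference coefficient set for the 5%-criterion start day of the spring paper-mulberry pollen season in Islamabad, fitted on 2004-2015 observations.",
  "window": {"start": "01-28", "end": "03-10"},
  "variables": ["T", "H", "Rf", "Cc", "Sd", "Wd", "Wg"],
  "intercept": 177.358,
  "coefficients": {
    "T": -4.409,
    "H": -0.491,
    "Rf": 0.011,
    "Cc": -0.391,
    "Sd": -0.098,
    "Wd": 0.154,
    "Wg": 2.186
  }
}
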