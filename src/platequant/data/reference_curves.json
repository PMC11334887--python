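[
  {
    "method": "smartphone",
    "sample": "4",
    "slope": 0.8118,
    "intercept": 113.25,
    "r_squared": 0.9832,
    "n_points": 5,
    "channel_or_mode": "B"
  },
  {
    "method": "smartphone",
    "sample": "9",
    "slope": 0.752,
    "intercept": 121.96,
    "r_squared": 0.9717,
    "n_points": 5,
    "channel_or_mode": "B"
  },
  {
    "method": "microplate_reader",
    "sample": "4",
    "slope": 0.006,
    "intercept": 0.5571,
    "r_squared": 0.9793,
    "n_points": 5,
    "channel_or_mode": "absorbance"
  },
  {
    "method": "microplate_reader",
    "sample": "9",
    "slope": 0.0048,
    "intercept": 0.5669,
    "r_squared": 0.9757,
    "n_points": 5,
    "channel_or_mode": "absorbance"
  }
]
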