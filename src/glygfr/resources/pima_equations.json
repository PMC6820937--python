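{
  "name": "pima",
  "scaling": {"age": 10.0, "hba1c": 1.0, "fpg": 100.0, "scr": 1.0},
  "strata": [
    {"sex": "F", "scr_lo": 0.0, "scr_hi": 0.55, "intercept": 4.8623,
     "coefficients": {"age": -0.1377, "hba1c": 0.0290, "fpg": 0.0607, "scr": -0.0360}},
    {"sex": "F", "scr_lo": 0.55, "scr_hi": 0.62, "intercept": 4.8435,
     "coefficients": {"age": -0.1178, "hba1c": 0.0268, "fpg": 0.0480, "scr": -0.0039}},
    {"sex": "F", "scr_lo": 0.62, "scr_hi": 0.72, "intercept": 4.7982,
     "coefficients": {"age": -0.1104, "hba1c": 0.0306, "fpg": 0.0417, "scr": -0.1263}},
    {"sex": "F", "scr_lo": 0.72, "scr_hi": Infinity, "intercept": 4.7916,
     "coefficients": {"age": -0.0928, "hba1c": -0.0014, "fpg": 0.0671, "scr": -0.2460}},
    {"sex": "M", "scr_lo": 0.0, "scr_hi": 0.70, "intercept": 4.9756,
     "coefficients": {"age": -0.0752, "hba1c": 0.0357, "fpg": 0.0259, "scr": -0.1160}},
    {"sex": "M", "scr_lo": 0.70, "scr_hi": 0.79, "intercept": 4.9666,
     "coefficients": {"age": -0.1075, "hba1c": 0.0110, "fpg": 0.0634, "scr": -0.2750}},
    {"sex": "M", "scr_lo": 0.79, "scr_hi": 0.90, "intercept": 4.976,
     "coefficients": {"age": -0.1406, "hba1c": -0.0385, "fpg": 0.0074, "scr": -0.1463}},
    {"sex": "M", "scr_lo": 0.90, "scr_hi": Infinity, "intercept": 5.0159,
     "coefficients": {"age": -0.1235, "hba1c": 0.0328, "fpg": -0.0236, "scr": -0.1771}}
  ]
}
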