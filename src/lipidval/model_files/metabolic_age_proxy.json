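{
  "name": "metabolic_age_proxy",
  "kind": "linear",
  "response": "metabolic_age",
  "intercept": -39.156,
  "terms": {
    "age": 0.541,
    "bmi": 2.394,
    "male": -7.326
  }
}
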