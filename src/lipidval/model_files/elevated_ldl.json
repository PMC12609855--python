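{
  "name": "elevated_ldl",
  "endpoint": "ldl",
  "intercept": -2.6091,
  "terms": {
    "male": 0.5542,
    "metabolic_age": 0.0155
  },
  "provenance": "updated_eq1"
}
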