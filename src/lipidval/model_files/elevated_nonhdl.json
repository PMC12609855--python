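{
  "name": "elevated_nonhdl",
  "endpoint": "nonhdl",
  "intercept": -3.1255,
  "terms": {
    "male": 0.9008,
    "metabolic_age": 0.0294,
    "dbp": 0.0100
  },
  "provenance": "updated_eq2"
}
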