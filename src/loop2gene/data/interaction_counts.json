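{
  "interacting": 2135,
  "prioritised": 387,
  "pan_cancer_drivers": 85,
  "pan_in_prioritised": 55,
  "ec_drivers": 28,
  "ec_in_prioritised": 19
}
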