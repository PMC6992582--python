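{
  "label": "multicenter-validation-model",
  "intercept": -2.728414,
  "age_center": 39.414,
  "b_ej_noa_age": -0.138868,
  "b_surg_noa_age": -0.13032,
  "s_ej_noa": 0.4928267,
  "g_anat_andro": 0.0807783,
  "g_gen_anat": 0.3765617,
  "platform_note": "Anatolia and Androfert used NGS; GENERA used qPCR",
  "stderr": {
    "intercept": 0.183,
    "b_ej_noa_age": 0.007,
    "b_surg_noa_age": 0.027,
    "s_ej_noa": 0.179,
    "g_anat_andro": 0.105,
    "g_gen_anat": 0.068
  }
}
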