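{
 "reference_dose_rate_cGy_per_mCi_h": {
  "value": 4.038,
  "unc": 0.064
 },
 "air_kerma_strength_U_per_mCi": {
  "value": 3.632,
  "unc": 0.086
 },
 "dose_rate_constant_cGy_per_h_per_U": {
  "value": 1.112,
  "unc": 0.029
 },
 "anisotropy_constant": {
  "value": 0.969,
  "unc": 0.007
 },
 "double_exponential_g_at_0": {
  "value": 0.994,
  "unc": null
 }
}
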