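{
 "model": "surrogate-v1",
 "reference_age": 40.0,
 "structures": {
  "hippocampus": {
   "mean_age40": 0.005,
   "slope_per_year": -1.5e-05,
   "sd": 0.0006,
   "direction": -1
  },
  "amygdala": {
   "mean_age40": 0.0022,
   "slope_per_year": -6e-06,
   "sd": 0.0003,
   "direction": -1
  },
  "inferior_lateral_ventricle": {
   "mean_age40": 0.0006,
   "slope_per_year": 1.2e-05,
   "sd": 0.0004,
   "direction": 1
  }
 },
 "logistic_scale": 2.0
}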