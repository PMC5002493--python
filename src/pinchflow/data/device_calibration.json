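{
 "458,400,70.71,30,60,26,23,50,147,60,20,8": {
  "folded_length": 15.0,
  "beta_slope": -4.472250168766302,
  "resolution_scale": 0.5,
  "beta0": 0.2493050543611755
 }
}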