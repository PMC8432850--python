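{
  "n_patients": 640,
  "seed": 0,
  "group_weights": [0.3421875, 0.190625, 0.2421875, 0.178125, 0.0203125, 0.0265625],
  "shift_prob": 0.9,
  "shift_sd": 16.0
}
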