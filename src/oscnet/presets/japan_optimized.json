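{
  "role3": "normal",
  "t_ilum3": 6.37,
  "t_start": 3.78,
  "t_end": 12.10,
  "t_max": 20.23,
  "alpha": 0.849,
  "beta": 0.251
}
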