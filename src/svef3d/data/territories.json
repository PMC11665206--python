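{
  "LAD": [1, 2, 7, 8, 13, 14, 17],
  "RCA": [3, 4, 9, 10, 15],
  "LCX": [5, 6, 11, 12, 16]
}
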