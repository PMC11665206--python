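{
  "normal": {"n": 320, "mean": 52.7, "sd": 15.0},
  "abnormal": {"n": 241, "mean": 35.5, "sd": 14.4},
  "comment": "Segmental EF (%) group moments for 2DE-normal vs 2DE-abnormal (hypokinetic + akinetic pooled) LV segments; inputs to the binormal ROC simulation."
}
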