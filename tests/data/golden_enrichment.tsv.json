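{
  "denominator_mode": "measured",
  "genes_measured": {
    "S1": 2,
    "S2": 2
  },
  "dropped_sets": []
}
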