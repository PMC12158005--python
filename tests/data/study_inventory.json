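{
  "known_mirnas": 342,
  "novel_mirnas": 404,
  "phas21_loci": 620,
  "phas24_loci": 34,
  "triggered_phas_loci": 526,
  "trigger_mirnas": 515,
  "model1_pairs": 2352,
  "model2_pairs": 3553
}
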