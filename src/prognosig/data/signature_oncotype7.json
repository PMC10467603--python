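{
  "name": "oncotype7",
  "genes": [
    {"gene": "BGN", "direction": "unfavorable"},
    {"gene": "FAP", "direction": "unfavorable"},
    {"gene": "INHBA", "direction": "unfavorable"},
    {"gene": "GADD45B", "direction": "unfavorable"},
    {"gene": "MYBL2", "direction": "favorable"},
    {"gene": "KI67", "direction": "favorable"},
    {"gene": "MYC", "direction": "favorable"}
  ],
  "cutoffs": {},
  "score_cutoff": {}
}
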