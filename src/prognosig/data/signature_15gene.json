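{
  "name": "15gene",
  "genes": [
    {"gene": "BET1L", "direction": "unfavorable"},
    {"gene": "CD2BP2", "direction": "unfavorable"},
    {"gene": "CD40LG", "direction": "unfavorable"},
    {"gene": "JUP", "direction": "unfavorable"},
    {"gene": "KCND2", "direction": "unfavorable"},
    {"gene": "SNAPC5", "direction": "unfavorable"},
    {"gene": "TMEM86B", "direction": "unfavorable"},
    {"gene": "TRIP10", "direction": "unfavorable"},
    {"gene": "ZNF785", "direction": "unfavorable"},
    {"gene": "ATOH1", "direction": "favorable"},
    {"gene": "FAM173B", "direction": "favorable"},
    {"gene": "GGT6", "direction": "favorable"},
    {"gene": "MTF1", "direction": "favorable"},
    {"gene": "TBC1D3H", "direction": "favorable"},
    {"gene": "UNC13B", "direction": "favorable"}
  ],
  "cutoffs": {},
  "score_cutoff": {}
}
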