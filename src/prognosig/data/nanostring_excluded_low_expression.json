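{
  "description": "Panel genes excluded from the 61-gene validation assay for very low average expression (<10 counts/sample).",
  "threshold_counts_per_sample": 10,
  "genes": ["CCDC96", "MRPL22", "SPATS1", "CFC1B", "GRIN3B", "MYLK2", "RTP3", "SLC6A13", "TRDN"]
}
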