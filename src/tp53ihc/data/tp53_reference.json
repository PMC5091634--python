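{
  "transcript": "canonical 393-aa p53 (major TP53 transcript, CDS exons 2-11)",
  "protein_length_aa": 393,
  "cds_length_nt": 1182,
  "domains": {
    "tad": [1, 42],
    "dbd": [102, 292],
    "tmd": [323, 356],
    "nls": [316, 325],
    "do7_epitope": [19, 26]
  },
  "nmd_ca_max_codon": 213,
  "expressed_min_codon": 245,
  "cy_length_range": [292, 306],
  "splice_window_nt": 2,
  "cds_exon_boundaries": {
    "comment": "1-based closed coding (c.) intervals of the ten coding exons",
    "exons": [
      [1, 74],
      [75, 96],
      [97, 375],
      [376, 559],
      [560, 672],
      [673, 782],
      [783, 919],
      [920, 993],
      [994, 1100],
      [1101, 1182]
    ]
  }
}
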