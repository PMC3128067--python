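{
  "description": "Unified nearest-neighbour Watson-Crick stack free energies, dG37 in kcal/mol (1 M NaCl). Keys are the 10 unique dinucleotide steps read 5'->3' on the probe strand; the remaining 6 steps follow by reverse-complement symmetry. Initiation terms are per duplex terminus, by the terminal base-pair class.",
  "version": "unified-1998",
  "stack_dG37": {
    "AA": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45,
    "GT": -1.44,
    "CT": -1.28,
    "GA": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84
  },
  "initiation_dG37": {
    "GC": 0.98,
    "AT": 1.03
  },
  "internal_mismatch_dG37": 3.0
}
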