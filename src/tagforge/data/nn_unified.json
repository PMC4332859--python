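{
  "name": "unified-oligonucleotide-nn-1998",
  "comment": "Unified nearest-neighbor parameters for DNA/DNA duplexes in 1 M NaCl. dH in kcal/mol, dS in cal/(mol.K). Stacks keyed by the top-strand dinucleotide 5'->3'; the ten unique Watson-Crick stacks are listed, others resolve via reverse complement.",
  "stacks": {
    "AA": {"dH": -7.9, "dS": -22.2},
    "AT": {"dH": -7.2, "dS": -20.4},
    "TA": {"dH": -7.2, "dS": -21.3},
    "CA": {"dH": -8.5, "dS": -22.7},
    "GT": {"dH": -8.4, "dS": -22.4},
    "CT": {"dH": -7.8, "dS": -21.0},
    "GA": {"dH": -8.2, "dS": -22.2},
    "CG": {"dH": -10.6, "dS": -27.2},
    "GC": {"dH": -9.8, "dS": -24.4},
    "GG": {"dH": -8.0, "dS": -19.9}
  },
  "initiation": {
    "GC": {"dH": 0.1, "dS": -2.8},
    "AT": {"dH": 2.3, "dS": 4.1}
  },
  "defaults": {
    "strand_concentration_molar": 2.5e-7,
    "monovalent_salt_molar": 0.05
  }
}
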