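{
  "comment": "Unified nearest-neighbor DNA/DNA parameters (SantaLucia 1998 consensus set). Stacks keyed by the plus-strand dinucleotide 5'->3'; values are [dH kcal/mol, dS cal/(mol K)]. Complementary stacks share values by duplex symmetry. Initiation terms keyed by the terminal base-pair class.",
  "stacks": {
    "AA": [-7.9, -22.2],
    "TT": [-7.9, -22.2],
    "AT": [-7.2, -20.4],
    "TA": [-7.2, -21.3],
    "CA": [-8.5, -22.7],
    "TG": [-8.5, -22.7],
    "GT": [-8.4, -22.4],
    "AC": [-8.4, -22.4],
    "CT": [-7.8, -21.0],
    "AG": [-7.8, -21.0],
    "GA": [-8.2, -22.2],
    "TC": [-8.2, -22.2],
    "CG": [-10.6, -27.2],
    "GC": [-9.8, -24.4],
    "GG": [-8.0, -19.9],
    "CC": [-8.0, -19.9]
  },
  "init": {
    "AT": [2.3, 4.1],
    "GC": [0.1, -2.8]
  }
}
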