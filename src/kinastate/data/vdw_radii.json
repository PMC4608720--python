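{
  "comment": "Per-element van der Waals radii (Angstrom, Bondi-style values) and atomic masses (Da). Override by passing a custom table to read_structure / Topology construction.",
  "radii": {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.9,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "MN": 2.05, "FE": 2.05, "CU": 1.4, "B": 1.92, "X": 1.7
  },
  "masses": {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971, "NA": 22.99, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "MN": 54.938, "FE": 55.845, "CU": 63.546, "B": 10.81,
    "X": 12.011
  }
}
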