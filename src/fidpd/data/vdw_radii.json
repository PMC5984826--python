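{
  "comment": "Van der Waals radii in Angstrom, CHARMM22-derived per-element values with an element fallback; keys are upper-case element symbols. 'overrides' maps 'RESNAME:ATOMNAME' to a radius.",
  "default": 1.70,
  "radii": {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
    "NA": 1.36,
    "MG": 1.19,
    "K": 1.76,
    "CA": 1.37,
    "MN": 1.40,
    "FE": 1.30,
    "CO": 1.40,
    "NI": 1.40,
    "CU": 1.40,
    "ZN": 1.09
  },
  "overrides": {}
}
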