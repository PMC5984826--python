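{
  "comment": "Single-bond covalent radii in Angstrom (classic Pauling/Cordero-style values); keys are upper-case element symbols. 'overrides' maps 'RESNAME:ATOMNAME' to a radius.",
  "default": 0.77,
  "radii": {
    "H": 0.32,
    "B": 0.82,
    "C": 0.77,
    "N": 0.75,
    "O": 0.73,
    "F": 0.71,
    "P": 1.06,
    "S": 1.05,
    "CL": 0.99,
    "SE": 1.17,
    "BR": 1.14,
    "I": 1.33,
    "NA": 1.54,
    "MG": 1.30,
    "K": 1.96,
    "CA": 1.74,
    "MN": 1.39,
    "FE": 1.25,
    "CO": 1.26,
    "NI": 1.21,
    "CU": 1.38,
    "ZN": 1.25
  },
  "overrides": {}
}
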