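{
  "_comment": "Bondi-style van der Waals radii in Angstrom, by element symbol. Interface labels depend on these values; override via config if needed.",
  "H": 1.2,
  "C": 1.7,
  "N": 1.55,
  "O": 1.52,
  "F": 1.47,
  "P": 1.8,
  "S": 1.8,
  "CL": 1.75,
  "BR": 1.85,
  "I": 1.98,
  "SE": 1.9,
  "ZN": 1.39,
  "FE": 1.52,
  "MG": 1.73,
  "CA": 2.31,
  "NA": 2.27,
  "K": 2.75,
  "MN": 1.61,
  "CU": 1.4,
  "default": 1.7
}
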