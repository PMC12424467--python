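{
  "_comment": "Monoisotopic atomic masses (Da) and mass numbers of the most abundant isotope, CODATA/IUPAC 2021 values. Used for mass-defect base units and the brute-force formula mass oracle.",
  "H":  {"mass": 1.00782503207,  "number": 1},
  "B":  {"mass": 11.0093054,     "number": 11},
  "C":  {"mass": 12.0,           "number": 12},
  "N":  {"mass": 14.0030740048,  "number": 14},
  "O":  {"mass": 15.9949146196,  "number": 16},
  "F":  {"mass": 18.99840322,    "number": 19},
  "Na": {"mass": 22.9897692809,  "number": 23},
  "Si": {"mass": 27.9769265325,  "number": 28},
  "P":  {"mass": 30.97376163,    "number": 31},
  "S":  {"mass": 31.97207100,    "number": 32},
  "Cl": {"mass": 34.96885268,    "number": 35},
  "K":  {"mass": 38.96370668,    "number": 39},
  "Br": {"mass": 78.9183371,     "number": 79},
  "I":  {"mass": 126.904473,     "number": 127}
}
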