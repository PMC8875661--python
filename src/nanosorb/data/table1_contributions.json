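{
  "description": "Reference per-term mean percentage contributions of intermolecular interactions to adsorption onto BP in the aqueous phase. Columns: direct models on |Ead| and logK; logK decomposed into entropic (TdS) and enthalpic (Ead_enthalpic) parts; logK decomposed into water-cavity (dG_H2O) and gaseous-interaction (dG_gaseous) parts. The sum row covers the five explicit descriptor terms only.",
  "terms": ["eE", "sS", "aA", "bB", "vV"],
  "columns": {
    "absEad":        {"eE": 23,  "sS": -26, "aA": 1,  "bB": 3,   "vV": 88},
    "logK":          {"eE": 17,  "sS": 20,  "aA": 0,  "bB": -1,  "vV": 111},
    "TdS":           {"eE": -47, "sS": 93,  "aA": -3, "bB": -11, "vV": -126},
    "Ead_enthalpic": {"eE": 62,  "sS": -70, "aA": 3,  "bB": 9,   "vV": 239},
    "dG_H2O":        {"eE": -5,  "sS": -8,  "aA": 2,  "bB": -1,  "vV": -49},
    "dG_gaseous":    {"eE": 21,  "sS": 30,  "aA": -2, "bB": -1,  "vV": 162}
  },
  "sum_row": {
    "absEad": 89, "logK": 147, "TdS": -94, "Ead_enthalpic": 243,
    "dG_H2O": -61, "dG_gaseous": 210
  }
}
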