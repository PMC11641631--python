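{
  "comment": "Published per-component regression model for AAindex property EISD840101 (consensus normalized hydrophobicity scale), as distributed with the original ncAA property database. Coefficients are zero for components outside the selected set. Used for the 4-hydroxyproline worked example and as a reference fixture; not produced by this package's training code.",
  "accession": "EISD840101",
  "description": "Consensus normalized hydrophobicity scale",
  "f_star": 2.4,
  "r_jn": 0.924,
  "r_insample": 0.953,
  "p_num": 10,
  "rmse": 0.282,
  "constant": 1.629829,
  "coefficients": {
    "dblO": 0.0,
    "anyO": -0.563688,
    "aliphN": -0.556289,
    "aromN": 0.163592,
    "dblN": 0.452579,
    "aliphC": 0.11307,
    "aromC": 0.14883,
    "chiralC": 0.0,
    "S": -0.248443,
    "ring1": -0.290756,
    "ring2": -0.688098,
    "dbl": 0.0,
    "plus": -1.168294
  },
  "selected": ["anyO", "aliphN", "aromN", "dblN", "aliphC", "aromC", "S", "ring1", "ring2", "plus"],
  "coefficient_f_values": {
    "anyO": 507.614,
    "aliphN": 120.263,
    "aromN": 9.014,
    "dblN": 11.118,
    "aliphC": 56.734,
    "aromC": 111.808,
    "S": 22.228,
    "ring1": 68.744,
    "ring2": 44.738,
    "plus": 189.686
  },
  "coefficient_sd": {
    "anyO": 0.025,
    "aliphN": 0.05,
    "aromN": 0.054,
    "dblN": 0.135,
    "aliphC": 0.015,
    "aromC": 0.014,
    "S": 0.052,
    "ring1": 0.035,
    "ring2": 0.102,
    "plus": 0.084
  },
  "hyp_worked_example": {
    "code": "HYP",
    "smiles": "O[C@H]1CN[C@@H](C1)C(O)=O",
    "components": {
      "dblO": 1,
      "anyO": 3,
      "aliphN": 1,
      "aromN": 0,
      "dblN": 0,
      "aliphC": 5,
      "aromC": 0,
      "chiralC": 2,
      "S": 0,
      "ring1": 1,
      "ring2": 0,
      "dbl": 1,
      "plus": 0
    },
    "predicted_value": -0.34293,
    "display": "-0.343 ± 0.282"
  },
  "threshold_scan": [
    {"f_threshold": 1.0, "r": 0.997, "r_jn": 0.85, "p_num": 11},
    {"f_threshold": 2.0, "r": 0.997, "r_jn": 0.848, "p_num": 10},
    {"f_threshold": 2.4, "r": 0.953, "r_jn": 0.924, "p_num": 10},
    {"f_threshold": 3.0, "r": 0.953, "r_jn": 0.89, "p_num": 3}
  ]
}
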