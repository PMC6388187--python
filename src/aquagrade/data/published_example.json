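{
  "comment": "Worked six-well example published with the GB/T 14848-93 fuzzy evaluation study: well Q6's 9x5 fuzzy relation matrix and normalized weight vector (indicator order TH, TDS, NO2, NO3, NH4, Mn, Fe, Cl, SO4), its composite membership vector, and the full panel's composite vectors with assigned grades.",
  "indicator_order": ["TH", "TDS", "NO2", "NO3", "NH4", "Mn", "Fe", "Cl", "SO4"],
  "q6": {
    "relation": [
      [0.063, 0.937, 0, 0, 0],
      [0.565, 0.435, 0, 0, 0],
      [0.667, 0.333, 0, 0, 0],
      [0.533, 0.467, 0, 0, 0],
      [1, 0, 0, 0, 0],
      [1, 0, 0, 0, 0],
      [1, 0, 0, 0, 0],
      [1, 0, 0, 0, 0],
      [0.920, 0.080, 0, 0, 0]
    ],
    "weights": [0.426, 0.185, 0.043, 0.111, 0.031, 0.008, 0.018, 0.032, 0.146],
    "composite": [0.442, 0.558, 0, 0, 0],
    "grade": 2
  },
  "panel": {
    "Q1": {"degrees": [0.085, 0.031, 0.568, 0.005, 0.311], "grade": 3},
    "Q2": {"degrees": [0.303, 0.670, 0, 0, 0], "grade": 2},
    "Q3": {"degrees": [0.064, 0.443, 0.171, 0.321, 0], "grade": 2},
    "Q4": {"degrees": [0.059, 0.361, 0.424, 0.156, 0], "grade": 3},
    "Q5": {"degrees": [0.225, 0.429, 0.319, 0, 0], "grade": 2},
    "Q6": {"degrees": [0.442, 0.558, 0, 0, 0], "grade": 2}
  },
  "facies_labels": {
    "Q1": "Ca-HCO3-SO4", "Q2": "Ca-HCO3-SO4",
    "Q3": "Ca-HCO3", "Q4": "Ca-HCO3", "Q5": "Ca-HCO3", "Q6": "Ca-HCO3"
  }
}
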