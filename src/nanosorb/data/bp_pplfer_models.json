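{
  "logK_gaseous": {
    "endpoint": "logK_gaseous",
    "phase": "gaseous",
    "descriptor_set": ["E", "S", "A", "B", "L"],
    "intercept": 0.2,
    "coefficients": {"E": -0.0076, "S": -1.1, "A": -1.1, "B": 1.4, "L": 1.5},
    "n_train": 33,
    "stats": {
      "r2_adj": 0.96, "rmse_train": 0.35, "q2_loo": 0.95, "q2_kfold": 0.95,
      "n_ext": 8, "rmse_ext": 0.35, "q2_ext": 0.97
    }
  },
  "logK_aqueous": {
    "endpoint": "logK_aqueous",
    "phase": "aqueous",
    "descriptor_set": ["E", "S", "A", "B", "V"],
    "intercept": -1.7,
    "coefficients": {"E": 0.65, "S": 0.75, "A": 0.048, "B": -0.095, "V": 4.0},
    "n_train": 33,
    "stats": {
      "r2_adj": 0.87, "rmse_train": 0.46, "q2_loo": 0.83, "q2_kfold": 0.82,
      "n_ext": 8, "rmse_ext": 0.43, "q2_ext": 0.90
    }
  },
  "absEad_gaseous": {
    "endpoint": "absEad_gaseous",
    "phase": "gaseous",
    "descriptor_set": ["E", "S", "A", "B", "L"],
    "intercept": 6.0,
    "coefficients": {"E": 1.4, "S": -7.4, "A": 1.2, "B": 6.6, "L": 3.4},
    "n_train": 33,
    "stats": {
      "r2_adj": 0.97, "rmse_train": 0.62, "q2_loo": 0.96, "q2_kfold": 0.96,
      "n_ext": 8, "rmse_ext": 0.61, "q2_ext": 0.97
    }
  },
  "absEad_aqueous": {
    "endpoint": "absEad_aqueous",
    "phase": "aqueous",
    "descriptor_set": ["E", "S", "A", "B", "V"],
    "intercept": 1.5,
    "coefficients": {"E": 3.5, "S": -3.8, "A": 0.89, "B": 1.7, "V": 13.0},
    "n_train": 33,
    "stats": {
      "r2_adj": 0.96, "rmse_train": 0.66, "q2_loo": 0.95, "q2_kfold": 0.94,
      "n_ext": 8, "rmse_ext": 0.73, "q2_ext": 0.96
    }
  }
}
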