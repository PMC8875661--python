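[
  {
    "no": 1, "label": "SWCNT (literature)", "nanomaterial": "SWCNT", "phase": "aqueous",
    "n_train": 30, "r2_train": 0.87, "abraham": true,
    "intercept": -1.3,
    "coefficients": {"E": 0.40, "S": 0.36, "A": 0.93, "B": -3.9, "V": 2.8}
  },
  {
    "no": 2, "label": "MWCNT (literature)", "nanomaterial": "MWCNT", "phase": "aqueous",
    "n_train": 29, "r2_train": 0.83, "abraham": true,
    "intercept": -4.3,
    "coefficients": {"S": 0.61, "A": 0.050, "B": -0.48, "V": 4.5}
  },
  {
    "no": 3, "label": "MWCNT (literature, alternate)", "nanomaterial": "MWCNT", "phase": "aqueous",
    "n_train": 28, "r2_train": 0.93, "abraham": true,
    "intercept": -1.3,
    "coefficients": {"E": 0.043, "S": 1.7, "A": -0.37, "B": -2.7, "V": 4.1}
  },
  {
    "no": 4, "label": "Graphene (literature)", "nanomaterial": "graphene", "phase": "aqueous",
    "n_train": 29, "r2_train": 0.89, "abraham": true,
    "intercept": -1.4,
    "coefficients": {"E": 0.11, "S": 1.4, "A": 0.42, "B": -3.8, "V": 2.2}
  },
  {
    "no": 5, "label": "Graphene (literature, charge-descriptor model)", "nanomaterial": "graphene", "phase": "aqueous",
    "n_train": 35, "r2_train": 0.88, "abraham": false,
    "equation": "logK = -1.8*eps_alpha - 1.2*eps_beta + 1.3*q_plus - 1.5*q_minus + 1.0*V - 1.6*pi + 42"
  },
  {
    "no": 6, "label": "Graphene oxide (literature)", "nanomaterial": "graphene oxide", "phase": "aqueous",
    "n_train": 36, "r2_train": 0.84, "abraham": true,
    "intercept": -1.4,
    "coefficients": {"E": 0.29, "S": 0.28, "A": -0.19, "B": -2.6, "V": 2.6}
  },
  {
    "no": 7, "label": "Graphene oxide (literature, alternate)", "nanomaterial": "graphene oxide", "phase": "aqueous",
    "n_train": 36, "r2_train": 0.92, "abraham": true,
    "intercept": -1.7,
    "coefficients": {"E": 0.93, "S": 0.060, "A": -0.38, "B": -1.9, "V": 2.2}
  },
  {
    "no": 8, "label": "BP (this study)", "nanomaterial": "BP", "phase": "aqueous",
    "n_train": 33, "r2_train": 0.87, "abraham": true,
    "intercept": -1.7,
    "coefficients": {"E": 0.65, "S": 0.75, "A": 0.048, "B": -0.095, "V": 4.0}
  },
  {
    "no": 9, "label": "BP (this study)", "nanomaterial": "BP", "phase": "gaseous",
    "n_train": 33, "r2_train": 0.96, "abraham": true,
    "intercept": 0.2,
    "coefficients": {"E": -0.0076, "S": -1.1, "A": -1.1, "B": 1.4, "L": 1.5}
  },
  {
    "no": 10, "label": "Graphene (this study)", "nanomaterial": "graphene", "phase": "aqueous",
    "n_train": 30, "r2_train": 0.86, "abraham": true,
    "intercept": -1.6,
    "coefficients": {"E": 0.42, "S": 1.0, "A": 0.26, "B": -0.78, "V": 4.0}
  },
  {
    "no": 11, "label": "Graphene (this study)", "nanomaterial": "graphene", "phase": "gaseous",
    "n_train": 30, "r2_train": 0.97, "abraham": true,
    "intercept": 0.052,
    "coefficients": {"E": -0.043, "S": -0.62, "A": -0.78, "B": -0.36, "L": 1.5}
  }
]
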