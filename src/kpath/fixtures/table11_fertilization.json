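{
  "description": "Fertilizing rates of the four treatments (g per 8.5 kg soil pot). Stored as metadata only; no computation uses it.",
  "treatments": {
    "OPT": {"urea": 6.65, "Na2PO4.2H2O": 11.72, "KCl": 6.83, "CaCO3": 2.13, "H3BO3": 1.00, "ZnSO4.7H2O": 1.87, "MgSO4.7H2O": 2.61},
    "SW":  {"urea": 6.65, "Na2PO4.2H2O": 11.72, "KCl": 6.83, "CaCO3": 2.13, "H3BO3": 1.00, "ZnSO4.7H2O": 1.87, "MgSO4.7H2O": 2.61},
    "SK":  {"urea": 6.65, "Na2PO4.2H2O": 11.72, "KCl": 0.0,  "CaCO3": 2.13, "H3BO3": 1.00, "ZnSO4.7H2O": 1.87, "MgSO4.7H2O": 2.61},
    "SWK": {"urea": 6.65, "Na2PO4.2H2O": 11.72, "KCl": 0.0,  "CaCO3": 2.13, "H3BO3": 1.00, "ZnSO4.7H2O": 1.87, "MgSO4.7H2O": 2.61}
  },
  "legend": {"OPT": "optimum fertilization", "SW": "water limited", "SK": "potassium limited", "SWK": "water and potassium limited"}
}
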