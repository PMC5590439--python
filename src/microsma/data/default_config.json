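{
  "material": {
    "Ea": 26300.0,
    "Em": 63000.0,
    "Mf": 9.0,
    "Ms": 18.4,
    "As": 29.3,
    "Af": 37.0,
    "CM": 8.0,
    "CA": 13.8,
    "sigma_s_cr": 100.0,
    "sigma_f_cr": 170.0,
    "eps_star": 0.067,
    "nu": 0.33
  },
  "scenario": {
    "name": "pseudoelastic_tension",
    "force": 70.0,
    "temperature": 60.0,
    "geometry": {"area": 0.125, "shear_modulus_factor": 1.28},
    "steps": 200
  },
  "quadrature": {"scheme": "bazant_oh_42"},
  "output": {"path": "result.csv", "format": "csv"},
  "seed": 0,
  "log_level": "INFO"
}
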