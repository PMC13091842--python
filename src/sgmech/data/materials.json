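{
  "_comment": "Calibrated material sets per device. Stent moduli in GPa, stresses in MPa; graft modulus in MPa, thickness in mm.",
  "VC": {
    "stent": {"E_A": 57.5, "nu_A": 0.3, "E_M": 47.8, "nu_M": 0.3,
              "eps_L": 0.063, "sigma_SL": 550.0, "sigma_EL": 620.0,
              "sigma_SU": 450.0, "sigma_EU": 250.0, "alpha": 0.0279},
    "graft": {"E": 1060.0, "thickness": 0.1}
  },
  "TBS": {
    "stent": {"E_A": 57.5, "nu_A": 0.3, "E_M": 47.8, "nu_M": 0.3,
              "eps_L": 0.063, "sigma_SL": 550.0, "sigma_EL": 620.0,
              "sigma_SU": 350.0, "sigma_EU": 270.0, "alpha": 0.0279},
    "graft": {"E": 520.0, "thickness": 0.115}
  },
  "CZA": {
    "stent": {"E_A": 57.5, "nu_A": 0.3, "E_M": 47.8, "nu_M": 0.3,
              "eps_L": 0.063, "sigma_SL": 550.0, "sigma_EL": 620.0,
              "sigma_SU": 350.0, "sigma_EU": 270.0, "alpha": 0.0279},
    "graft": {"E": 520.0, "thickness": 0.115}
  },
  "CTAG": {
    "stent": {"E_A": 34.5, "nu_A": 0.3, "E_M": 29.8, "nu_M": 0.3,
              "eps_L": 0.063, "sigma_SL": 500.0, "sigma_EL": 800.0,
              "sigma_SU": 400.0, "sigma_EU": 200.0, "alpha": 0.0279},
    "graft": {"E": 90.0, "thickness": 0.11}
  }
}
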