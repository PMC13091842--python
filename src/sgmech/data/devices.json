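{
  "_comment": "Device presets. Diameters, lengths, working ranges, wire and graft thicknesses and suture spacings follow published device tables; ring layout (n_crowns, amplitude, pitch) and the CZA working-range band are package ASSUMPTIONS, not published facts. Units mm; stress_free_increase is a fraction.",
  "VC": {
    "diameter": 34.0, "total_length": 178.0, "covered_length": 167.0,
    "working_range": [29.0, 31.0], "wire_diameter": 0.5,
    "graft_thickness": 0.1, "graft_element_size": 1.0,
    "suture_spacing": 1.0, "bonded": false,
    "stress_free_increase": 0.125,
    "ring": {"n_crowns": 5, "amplitude": 7.5, "pitch": 18.0},
    "proximal_ring": {"n_crowns": 8, "amplitude": 2.5,
                      "wire_diameter": 0.25, "axial_position": 4.0}
  },
  "TBS": {
    "diameter": 34.0, "total_length": 160.0, "covered_length": 142.0,
    "working_range": [30.0, 31.0], "wire_diameter": 0.5,
    "graft_thickness": 0.115, "graft_element_size": 1.0,
    "suture_spacing": 1.0, "bonded": false,
    "stress_free_increase": 0.37, "lateral_bar": true,
    "ring": {"n_crowns": 5, "amplitude": 7.5, "pitch": 18.0}
  },
  "CZA": {
    "diameter": 34.0, "total_length": 173.0, "covered_length": 161.0,
    "working_range": [29.0, 31.0], "wire_diameter": 0.5,
    "graft_thickness": 0.115, "graft_element_size": 1.0,
    "suture_spacing": 6.0, "bonded": false,
    "stress_free_increase": 0.0575,
    "ring": {"n_crowns": 5, "amplitude": 7.5, "pitch": 18.0}
  },
  "CTAG": {
    "diameter": 34.0, "total_length": 138.0, "covered_length": 133.0,
    "working_range": [27.0, 32.0], "wire_diameter": 0.5,
    "graft_thickness": 0.11, "graft_element_size": 0.75,
    "suture_spacing": 1.0, "bonded": true,
    "stress_free_increase": 0.0, "continuous_wire": true,
    "ring": {"n_crowns": 12, "amplitude": 5.0, "pitch": 10.0}
  }
}
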