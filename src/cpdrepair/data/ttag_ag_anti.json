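{
  "system_label": "TTAG AG-anti",
  "reference": "ground-state minimum",
  "bright_state_energy_eV": 4.95,
  "states": [
    {"label": "S1", "character": "LE", "transition_note": "pipi* (G)", "energy_eV": 4.95, "oscillator_strength": 0.097, "wavelength_nm": 250.7},
    {"label": "S2", "character": "LE", "transition_note": "npi* (T of CPD)", "energy_eV": 5.07, "oscillator_strength": 0.00104, "wavelength_nm": 244.5},
    {"label": "S3", "character": "LE", "transition_note": "npi* (T of CPD)", "energy_eV": 5.12, "oscillator_strength": 0.00165, "wavelength_nm": 242.0},
    {"label": "S4", "character": "LE", "transition_note": "pipi* (A)", "energy_eV": 5.15, "oscillator_strength": 0.070, "wavelength_nm": 240.7},
    {"label": "S5", "character": "LE", "transition_note": "pipi* (A)", "energy_eV": 5.28, "oscillator_strength": 0.00806, "wavelength_nm": 234.7},
    {"label": "S6", "character": "CT", "transition_note": "G -> A charge transfer (piG pi*A)", "energy_eV": 5.40, "oscillator_strength": 0.388, "wavelength_nm": 229.4}
  ],
  "points": [
    {"name": "FC", "kind": "minimum", "energy_eV": 4.95, "provenance": "printed",
     "geometry_notes": {}},
    {"name": "G*", "kind": "minimum", "energy_eV": 4.27, "provenance": "printed",
     "geometry_notes": {}},
    {"name": "MECP_G", "kind": "MECP", "energy_eV": 5.02, "provenance": "derived-from-text",
     "geometry_notes": {}},
    {"name": "A-G+", "kind": "minimum", "energy_eV": 4.15, "provenance": "derived-from-text",
     "geometry_notes": {}},
    {"name": "MECP_AG", "kind": "MECP", "energy_eV": 5.33, "provenance": "derived-from-text",
     "geometry_notes": {}},
    {"name": "TT-AG+", "kind": "minimum", "energy_eV": 2.93, "provenance": "derived-from-text",
     "geometry_notes": {}},
    {"name": "MECP_CPD", "kind": "MECP", "energy_eV": 3.03, "provenance": "upper-bound-from-text",
     "geometry_notes": {"C5...C5_A": 2.55, "C6-C6_A": 1.56}}
  ]
}
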