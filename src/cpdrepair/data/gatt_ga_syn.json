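{
  "system_label": "GATT GA-syn",
  "reference": "S1 G* minimum",
  "bright_state_energy_eV": null,
  "states": [
    {"label": "S4", "character": "LE", "transition_note": "pipi* (G)", "energy_eV": 5.00, "oscillator_strength": 0.056, "wavelength_nm": 248.0},
    {"label": "S7", "character": "CT", "transition_note": "A -> TT charge transfer", "energy_eV": 5.32, "oscillator_strength": 0.000425, "wavelength_nm": 233.1},
    {"label": "S10", "character": "CT", "transition_note": "G -> A charge transfer (piG pi*A)", "energy_eV": 5.60, "oscillator_strength": 0.015, "wavelength_nm": 221.4}
  ],
  "points": [
    {"name": "G*", "kind": "minimum", "energy_eV": 0.0, "provenance": "printed",
     "geometry_notes": {}},
    {"name": "MECP_G", "kind": "MECP", "energy_eV": 0.15, "provenance": "printed",
     "geometry_notes": {}}
  ],
  "floating_gaps": [
    {"from": "A-G+", "to": "MECP_AG", "gap_eV": 0.42, "provenance": "printed",
     "note": "MECP above the G+A- CT minimum; the minimum's own energy relative to G* is not published for this conformer"}
  ]
}
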