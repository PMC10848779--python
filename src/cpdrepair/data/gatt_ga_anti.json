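{
  "system_label": "GATT GA-anti",
  "reference": "S1 G* minimum",
  "bright_state_energy_eV": null,
  "states": [
    {"label": "S10", "character": "CT", "transition_note": "A -> TT charge transfer at the FC geometry", "energy_eV": 5.81, "oscillator_strength": null, "wavelength_nm": null}
  ],
  "points": [
    {"name": "G*", "kind": "minimum", "energy_eV": 0.0, "provenance": "printed",
     "geometry_notes": {}},
    {"name": "MECP_G", "kind": "MECP", "energy_eV": 0.50, "provenance": "printed",
     "geometry_notes": {}},
    {"name": "A-G+", "kind": "minimum", "energy_eV": -0.9, "provenance": "printed",
     "geometry_notes": {}},
    {"name": "MECP_AG", "kind": "MECP", "energy_eV": -1.15, "provenance": "derived-from-text",
     "geometry_notes": {}}
  ]
}
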