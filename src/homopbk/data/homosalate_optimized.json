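{
  "name": "homosalate",
  "molecular_weight": 262.344,
  "log_p": 6.34,
  "pka": 8.1,
  "ionization_class": "acid",
  "fraction_unbound": 0.014,
  "blood_cell_plasma_partition": 21.28,
  "endothelial_permeability": 1.9,
  "cellular_permeability": 4.83,
  "plasma_to_blood_cell_permeability": 0.15,
  "blood_cell_to_plasma_permeability": 0.15,
  "water_solubility": 0.4,
  "melting_point": -20.0
}
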