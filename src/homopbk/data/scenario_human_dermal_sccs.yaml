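scenario_id: human_dermal_sccs
description: 10% product, 17500 cm2, bi-daily for 30 days (103 ug/cm2/day); penetrated fractions 2/2.5/3.86/5.3%; population CI(5-95)%
species: human
route: dermal
fractions: [0.02, 0.025, 0.0386, 0.053]
area_cm2: 17500.0
doses_per_day: 2
n_days: 30
product_fraction: 0.10
population_n: 20
population_seed: 0
uncertainty:
  fraction_unbound: {mean: 0.014, sd: 0.0014, lower: 0.0001, upper: 1.0}
  intrinsic_clearance: {mean: 59.6, sd: 2.7, lower: 1.0, upper: 1000.0}
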