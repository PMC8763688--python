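scenario_id: clinical_must_mimic
description: Clinical maximal-usage mimic; 150 ug/cm2 on 19000 cm2; Day-1 single + Days 2-4 four applications at 2-h intervals; 2.48% delivery
species: human
route: dermal_clinical
fractions: [0.0248]
daily_dose_ug_cm2: 150.0
area_cm2: 19000.0
product_fraction: 0.10
application_times: [0.0, 24.0, 26.0, 28.0, 30.0, 48.0, 50.0, 52.0, 54.0, 72.0, 74.0, 76.0, 78.0]
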