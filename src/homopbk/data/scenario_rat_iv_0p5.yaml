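scenario_id: rat_iv_0p5
description: Single IV bolus 0.5 mg/kg to the reference rat (model qualification dose)
species: rat
route: iv_bolus
doses_mg_kg: [0.5]
t_end_h: 24.0
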