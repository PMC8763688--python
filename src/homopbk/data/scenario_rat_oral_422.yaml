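scenario_id: rat_oral_422
description: Repeated oral gavage 60/120/300/750 mg/kg/day for 49 days, bioavailability calibrated to 50%; last-day window
species: rat
route: oral
doses_mg_kg: [60.0, 120.0, 300.0, 750.0]
n_days: 49
fb_target: 0.5
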