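scenario_id: rat_oral_20_60_120
description: Repeated oral gavage 20/60/120 mg/kg/day for 49 days (alternative dose list), bioavailability 50%
species: rat
route: oral
doses_mg_kg: [20.0, 60.0, 120.0]
n_days: 49
fb_target: 0.5
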