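{
  "table_version": "1.0",
  "species": "human",
  "note": "Literature-style reference physiology for the European adult (60 kg, 163 cm, 30 y). Volumes in mL, flows as fractions of systemic cardiac output. Gallbladder and saliva are inert volume-only pools (flow 0). Composition fractions shared with the rat table; versioned packaged data.",
  "reference_body_weight_kg": 60.0,
  "reference_age_years": 30.0,
  "reference_height_cm": 163.0,
  "cardiac_output_l_per_h": 312.0,
  "hematocrit": 0.43,
  "body_density_g_per_ml": 1.05,
  "gfr_ml_min": 107.44,
  "organs": [
    {"name": "lung",    "volume_ml": 500.0,   "flow_fraction": 1.0,   "vascular_fraction": 0.15, "interstitial_fraction": 0.18, "f_ew": 0.336, "f_iw": 0.446, "f_nl": 0.022,  "f_np": 0.0128, "albumin_ratio": 0.212, "intracellular_ph": 7.0, "portal": false},
    {"name": "heart",   "volume_ml": 300.0,   "flow_fraction": 0.040, "vascular_fraction": 0.06, "interstitial_fraction": 0.16, "f_ew": 0.320, "f_iw": 0.456, "f_nl": 0.014,  "f_np": 0.0111, "albumin_ratio": 0.157, "intracellular_ph": 7.0, "portal": false},
    {"name": "brain",   "volume_ml": 1350.0,  "flow_fraction": 0.120, "vascular_fraction": 0.03, "interstitial_fraction": 0.16, "f_ew": 0.162, "f_iw": 0.620, "f_nl": 0.039,  "f_np": 0.0015, "albumin_ratio": 0.048, "intracellular_ph": 7.0, "portal": false},
    {"name": "muscle",  "volume_ml": 23500.0, "flow_fraction": 0.250, "vascular_fraction": 0.03, "interstitial_fraction": 0.12, "f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010,  "f_np": 0.0072, "albumin_ratio": 0.064, "intracellular_ph": 7.0, "portal": false},
    {"name": "adipose", "volume_ml": 12000.0, "flow_fraction": 0.050, "vascular_fraction": 0.02, "interstitial_fraction": 0.13, "f_ew": 0.135, "f_iw": 0.017, "f_nl": 0.853,  "f_np": 0.0016, "albumin_ratio": 0.049, "intracellular_ph": 7.0, "portal": false},
    {"name": "skin",    "volume_ml": 2600.0,  "flow_fraction": 0.050, "vascular_fraction": 0.02, "interstitial_fraction": 0.30, "f_ew": 0.382, "f_iw": 0.291, "f_nl": 0.060,  "f_np": 0.0044, "albumin_ratio": 0.277, "intracellular_ph": 7.0, "portal": false},
    {"name": "bone",    "volume_ml": 8500.0,  "flow_fraction": 0.050, "vascular_fraction": 0.04, "interstitial_fraction": 0.10, "f_ew": 0.100, "f_iw": 0.346, "f_nl": 0.017,  "f_np": 0.0017, "albumin_ratio": 0.100, "intracellular_ph": 7.0, "portal": false},
    {"name": "liver",   "volume_ml": 1550.0,  "flow_fraction": 0.065, "vascular_fraction": 0.11, "interstitial_fraction": 0.16, "f_ew": 0.161, "f_iw": 0.573, "f_nl": 0.014,  "f_np": 0.0240, "albumin_ratio": 0.086, "intracellular_ph": 7.0, "portal": false},
    {"name": "spleen",  "volume_ml": 170.0,   "flow_fraction": 0.015, "vascular_fraction": 0.22, "interstitial_fraction": 0.15, "f_ew": 0.207, "f_iw": 0.579, "f_nl": 0.0077, "f_np": 0.0113, "albumin_ratio": 0.097, "intracellular_ph": 7.0, "portal": true},
    {"name": "gut",     "volume_ml": 1000.0,  "flow_fraction": 0.145, "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.282, "f_iw": 0.475, "f_nl": 0.038,  "f_np": 0.0125, "albumin_ratio": 0.158, "intracellular_ph": 7.0, "portal": true},
    {"name": "kidney",  "volume_ml": 270.0,   "flow_fraction": 0.190, "vascular_fraction": 0.11, "interstitial_fraction": 0.20, "f_ew": 0.273, "f_iw": 0.483, "f_nl": 0.012,  "f_np": 0.0240, "albumin_ratio": 0.130, "intracellular_ph": 7.0, "portal": false},
    {"name": "gonads",  "volume_ml": 30.0,    "flow_fraction": 0.005, "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.330, "f_iw": 0.470, "f_nl": 0.017,  "f_np": 0.0120, "albumin_ratio": 0.100, "intracellular_ph": 7.0, "portal": false},
    {"name": "pancreas","volume_ml": 100.0,   "flow_fraction": 0.010, "vascular_fraction": 0.05, "interstitial_fraction": 0.16, "f_ew": 0.120, "f_iw": 0.664, "f_nl": 0.041,  "f_np": 0.0093, "albumin_ratio": 0.060, "intracellular_ph": 7.0, "portal": true},
    {"name": "stomach", "volume_ml": 150.0,   "flow_fraction": 0.010, "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.320, "f_iw": 0.470, "f_nl": 0.038,  "f_np": 0.0125, "albumin_ratio": 0.158, "intracellular_ph": 7.0, "portal": true},
    {"name": "gallbladder", "volume_ml": 20.0, "flow_fraction": 0.0,  "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.320, "f_iw": 0.470, "f_nl": 0.020,  "f_np": 0.0120, "albumin_ratio": 0.100, "intracellular_ph": 7.0, "portal": false},
    {"name": "saliva",  "volume_ml": 10.0,    "flow_fraction": 0.0,   "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.320, "f_iw": 0.470, "f_nl": 0.020,  "f_np": 0.0120, "albumin_ratio": 0.100, "intracellular_ph": 7.0, "portal": false}
  ],
  "arterial_blood_volume_ml": 1600.0,
  "venous_blood_volume_ml": 3300.0
}
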