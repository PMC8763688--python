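{
  "table_version": "1.0",
  "species": "rat",
  "note": "Literature-style reference physiology for a 0.23 kg adult rat. Volumes in mL, flows as fractions of systemic cardiac output. Composition fractions (extracellular/intracellular water, neutral lipid, neutral phospholipid) and tissue:plasma albumin ratios are representative values for tissue-partitioning prediction; versioned packaged data.",
  "reference_body_weight_kg": 0.23,
  "reference_age_years": 0.77,
  "cardiac_output_l_per_h": 4.7,
  "hematocrit": 0.45,
  "body_density_g_per_ml": 1.05,
  "gfr_ml_min_per_100g_kidney": 57.0,
  "organs": [
    {"name": "lung",    "volume_ml": 1.2,  "flow_fraction": 1.0,   "vascular_fraction": 0.15, "interstitial_fraction": 0.18, "f_ew": 0.336, "f_iw": 0.446, "f_nl": 0.022,  "f_np": 0.0128, "albumin_ratio": 0.212, "intracellular_ph": 7.0, "portal": false},
    {"name": "heart",   "volume_ml": 0.8,  "flow_fraction": 0.049, "vascular_fraction": 0.06, "interstitial_fraction": 0.16, "f_ew": 0.320, "f_iw": 0.456, "f_nl": 0.014,  "f_np": 0.0111, "albumin_ratio": 0.157, "intracellular_ph": 7.0, "portal": false},
    {"name": "brain",   "volume_ml": 1.6,  "flow_fraction": 0.020, "vascular_fraction": 0.03, "interstitial_fraction": 0.16, "f_ew": 0.162, "f_iw": 0.620, "f_nl": 0.039,  "f_np": 0.0015, "albumin_ratio": 0.048, "intracellular_ph": 7.0, "portal": false},
    {"name": "muscle",  "volume_ml": 101.0,"flow_fraction": 0.353, "vascular_fraction": 0.03, "interstitial_fraction": 0.12, "f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010,  "f_np": 0.0072, "albumin_ratio": 0.064, "intracellular_ph": 7.0, "portal": false},
    {"name": "adipose", "volume_ml": 16.0, "flow_fraction": 0.070, "vascular_fraction": 0.02, "interstitial_fraction": 0.13, "f_ew": 0.135, "f_iw": 0.017, "f_nl": 0.853,  "f_np": 0.0016, "albumin_ratio": 0.049, "intracellular_ph": 7.0, "portal": false},
    {"name": "skin",    "volume_ml": 40.0, "flow_fraction": 0.058, "vascular_fraction": 0.02, "interstitial_fraction": 0.30, "f_ew": 0.382, "f_iw": 0.291, "f_nl": 0.060,  "f_np": 0.0044, "albumin_ratio": 0.277, "intracellular_ph": 7.0, "portal": false},
    {"name": "bone",    "volume_ml": 17.0, "flow_fraction": 0.122, "vascular_fraction": 0.04, "interstitial_fraction": 0.10, "f_ew": 0.100, "f_iw": 0.346, "f_nl": 0.017,  "f_np": 0.0017, "albumin_ratio": 0.100, "intracellular_ph": 7.0, "portal": false},
    {"name": "liver",   "volume_ml": 9.2,  "flow_fraction": 0.021, "vascular_fraction": 0.11, "interstitial_fraction": 0.16, "f_ew": 0.161, "f_iw": 0.573, "f_nl": 0.014,  "f_np": 0.0240, "albumin_ratio": 0.086, "intracellular_ph": 7.0, "portal": false},
    {"name": "spleen",  "volume_ml": 0.5,  "flow_fraction": 0.010, "vascular_fraction": 0.22, "interstitial_fraction": 0.15, "f_ew": 0.207, "f_iw": 0.579, "f_nl": 0.0077, "f_np": 0.0113, "albumin_ratio": 0.097, "intracellular_ph": 7.0, "portal": true},
    {"name": "gut",     "volume_ml": 8.0,  "flow_fraction": 0.131, "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.282, "f_iw": 0.475, "f_nl": 0.038,  "f_np": 0.0125, "albumin_ratio": 0.158, "intracellular_ph": 7.0, "portal": true},
    {"name": "kidney",  "volume_ml": 1.84, "flow_fraction": 0.141, "vascular_fraction": 0.11, "interstitial_fraction": 0.20, "f_ew": 0.273, "f_iw": 0.483, "f_nl": 0.012,  "f_np": 0.0240, "albumin_ratio": 0.130, "intracellular_ph": 7.0, "portal": false},
    {"name": "gonads",  "volume_ml": 0.6,  "flow_fraction": 0.005, "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.330, "f_iw": 0.470, "f_nl": 0.017,  "f_np": 0.0120, "albumin_ratio": 0.100, "intracellular_ph": 7.0, "portal": false},
    {"name": "pancreas","volume_ml": 0.5,  "flow_fraction": 0.010, "vascular_fraction": 0.05, "interstitial_fraction": 0.16, "f_ew": 0.120, "f_iw": 0.664, "f_nl": 0.041,  "f_np": 0.0093, "albumin_ratio": 0.060, "intracellular_ph": 7.0, "portal": true},
    {"name": "stomach", "volume_ml": 1.1,  "flow_fraction": 0.010, "vascular_fraction": 0.04, "interstitial_fraction": 0.16, "f_ew": 0.320, "f_iw": 0.470, "f_nl": 0.038,  "f_np": 0.0125, "albumin_ratio": 0.158, "intracellular_ph": 7.0, "portal": true}
  ],
  "arterial_blood_volume_ml": 5.0,
  "venous_blood_volume_ml": 10.0
}
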