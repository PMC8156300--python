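{
  "_comment": "Illustrative healthy reference means by age band (synthetic placeholders, editable). rr_mean in breaths/min; rc_percent_mean and phase_mean per the pipeline's index definitions; lbi_mean dimensionless.",
  "deviation_fraction": 0.2,
  "etco2_range": [35.0, 45.0],
  "spo2_min": 95.0,
  "age_bands": [
    {"age_lo": 0,  "age_hi": 1,  "rr_mean": 40.0, "rc_percent_mean": 45.0, "lbi_mean": 1.1,  "phase_mean": 10.0},
    {"age_lo": 1,  "age_hi": 5,  "rr_mean": 26.0, "rc_percent_mean": 48.0, "lbi_mean": 1.08, "phase_mean": 8.0},
    {"age_lo": 5,  "age_hi": 12, "rr_mean": 20.0, "rc_percent_mean": 50.0, "lbi_mean": 1.05, "phase_mean": 6.0},
    {"age_lo": 12, "age_hi": 18, "rr_mean": 16.0, "rc_percent_mean": 50.0, "lbi_mean": 1.05, "phase_mean": 5.0},
    {"age_lo": 18, "age_hi": 120, "rr_mean": 14.0, "rc_percent_mean": 50.0, "lbi_mean": 1.05, "phase_mean": 5.0}
  ]
}
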