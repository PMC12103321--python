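{
  "version": "1.0",
  "comment": "Bundled reference dataset: printed inputs of the centrifugal-fractionation and spike-recovery experiments the package models. Used by fractoc.reproduce and the analysis scripts.",
  "fluid": {"density": 1.0, "viscosity": 1.0016, "temperature": 20.0},
  "ps_density": 1.05,
  "mixture": [
    {"polymer": "PS", "diameter_nm": 200.0, "mg_per_L": 5.0},
    {"polymer": "PS", "diameter_nm": 500.0, "mg_per_L": 5.0},
    {"polymer": "PS", "diameter_nm": 1000.0, "mg_per_L": 5.0}
  ],
  "runs": [
    {"name": "C1", "rcf_set": 2500.0, "rpm_set": 3727.0, "rcf_top": 1042.0, "rcf_bottom": 1976.0, "column_height_mm": 60.0, "duration_min": 14.0, "nominal_cutoff_nm": 1000.0},
    {"name": "C2", "rcf_set": 4000.0, "rpm_set": 4714.0, "rcf_top": 1668.0, "rcf_bottom": 3161.0, "column_height_mm": 60.0, "duration_min": 30.0, "nominal_cutoff_nm": 500.0}
  ],
  "pre_centrifugation_recoveries": {
    "toc_total_pct": {"value": 98.3, "u": 7.1, "nominal_mg_per_L": 15.0},
    "spes_500_pct": {"value": 108.3, "u": 10.2, "nominal_mg_per_L": 5.0},
    "spes_1000_pct": {"value": 105.0, "u": 8.2, "nominal_mg_per_L": 5.0}
  },
  "spike_recovery_table": {
    "spike": [
      {"polymer": "PS", "diameter_nm": 1000.0, "mg_per_L": 1.0},
      {"polymer": "PS", "diameter_nm": 50.0, "mg_per_L": 1.0}
    ],
    "net_toc_mg_per_L": {
      "UPW":   {"unfiltered": {"value": 1.712, "u": 0.014}, "filtered": {"value": 0.830, "u": 0.004}},
      "lake":  {"unfiltered": {"value": 1.637, "u": 0.131}, "filtered": {"value": 0.788, "u": 0.223}},
      "river": {"unfiltered": {"value": 1.538, "u": 0.325}, "filtered": {"value": 0.577, "u": 0.265}}
    },
    "native_toc_mg_per_L": {
      "UPW":   {"unfiltered": {"value": 0.028, "u": 0.003}, "filtered": {"value": 0.094, "u": 0.002}},
      "lake":  {"unfiltered": {"value": 0.872, "u": 0.098}, "filtered": {"value": 0.750, "u": 0.070}},
      "river": {"unfiltered": {"value": 0.202, "u": 0.139}, "filtered": {"value": 0.167, "u": 0.046}}
    }
  },
  "af4": {"injected_mass_ug": 150.0, "iso_threshold_pct": 70.0}
}
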