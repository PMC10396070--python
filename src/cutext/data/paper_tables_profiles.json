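{
  "presets": {
    "paper_tables": [
      {"name": "control", "modality": "written", "n": 20, "cu_mean": 18.5, "cu_sd": 9.32,
       "ratio_mean": 0.30, "ratio_sd": 0.05, "self_ref_rate": 0.15, "unambiguous_share": 0.81,
       "repeat_rate": 0.05, "false_start_rate": 0.0, "contraction_rate": 0.03, "unintelligible_rate": 0.0},
      {"name": "control", "modality": "spoken", "n": 20, "cu_mean": 19.5, "cu_sd": 5.5,
       "ratio_mean": 0.20, "ratio_sd": 0.05, "self_ref_rate": 1.55, "unambiguous_share": 0.82,
       "repeat_rate": 0.08, "false_start_rate": 0.01, "contraction_rate": 0.05, "unintelligible_rate": 0.005},
      {"name": "nfvPPA", "modality": "written", "n": 26, "cu_mean": 14.35, "cu_sd": 6.11,
       "ratio_mean": 0.43, "ratio_sd": 0.14, "self_ref_rate": 0.07, "unambiguous_share": 0.86,
       "repeat_rate": 0.03, "false_start_rate": 0.0, "contraction_rate": 0.02, "unintelligible_rate": 0.01},
      {"name": "nfvPPA", "modality": "spoken", "n": 26, "cu_mean": 16.85, "cu_sd": 5.67,
       "ratio_mean": 0.28, "ratio_sd": 0.12, "self_ref_rate": 0.96, "unambiguous_share": 0.88,
       "repeat_rate": 0.05, "false_start_rate": 0.03, "contraction_rate": 0.04, "unintelligible_rate": 0.01},
      {"name": "lvPPA", "modality": "written", "n": 28, "cu_mean": 12.0, "cu_sd": 8.15,
       "ratio_mean": 0.32, "ratio_sd": 0.13, "self_ref_rate": 0.27, "unambiguous_share": 0.83,
       "repeat_rate": 0.04, "false_start_rate": 0.0, "contraction_rate": 0.02, "unintelligible_rate": 0.01},
      {"name": "lvPPA", "modality": "spoken", "n": 28, "cu_mean": 19.14, "cu_sd": 5.64,
       "ratio_mean": 0.15, "ratio_sd": 0.06, "self_ref_rate": 2.8, "unambiguous_share": 0.81,
       "repeat_rate": 0.08, "false_start_rate": 0.03, "contraction_rate": 0.05, "unintelligible_rate": 0.01},
      {"name": "svPPA", "modality": "written", "n": 15, "cu_mean": 10.33, "cu_sd": 4.7,
       "ratio_mean": 0.44, "ratio_sd": 0.23, "self_ref_rate": 0.0, "unambiguous_share": 0.80,
       "repeat_rate": 0.03, "false_start_rate": 0.0, "contraction_rate": 0.02, "unintelligible_rate": 0.01},
      {"name": "svPPA", "modality": "spoken", "n": 15, "cu_mean": 14.27, "cu_sd": 4.74,
       "ratio_mean": 0.11, "ratio_sd": 0.05, "self_ref_rate": 7.29, "unambiguous_share": 0.76,
       "repeat_rate": 0.1, "false_start_rate": 0.02, "contraction_rate": 0.05, "unintelligible_rate": 0.005}
    ],
    "paper_tables_written": [
      {"name": "control", "modality": "written", "n": 20, "cu_mean": 18.5, "cu_sd": 9.32,
       "ratio_mean": 0.30, "ratio_sd": 0.05, "self_ref_rate": 0.15, "unambiguous_share": 0.81,
       "repeat_rate": 0.05, "false_start_rate": 0.0, "contraction_rate": 0.03, "unintelligible_rate": 0.0},
      {"name": "nfvPPA", "modality": "written", "n": 28, "cu_mean": 13.89, "cu_sd": 6.33,
       "ratio_mean": 0.42, "ratio_sd": 0.14, "self_ref_rate": 0.07, "unambiguous_share": 0.86,
       "repeat_rate": 0.03, "false_start_rate": 0.0, "contraction_rate": 0.02, "unintelligible_rate": 0.01},
      {"name": "lvPPA", "modality": "written", "n": 30, "cu_mean": 11.97, "cu_sd": 7.87,
       "ratio_mean": 0.32, "ratio_sd": 0.12, "self_ref_rate": 0.27, "unambiguous_share": 0.83,
       "repeat_rate": 0.04, "false_start_rate": 0.0, "contraction_rate": 0.02, "unintelligible_rate": 0.01},
      {"name": "svPPA", "modality": "written", "n": 17, "cu_mean": 10.0, "cu_sd": 4.5,
       "ratio_mean": 0.44, "ratio_sd": 0.22, "self_ref_rate": 0.0, "unambiguous_share": 0.80,
       "repeat_rate": 0.03, "false_start_rate": 0.0, "contraction_rate": 0.02, "unintelligible_rate": 0.01}
    ]
  }
}
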