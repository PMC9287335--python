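{
  "cohort_config": {
    "beta_by_site": {
      "7mer-1a": -0.2,
      "7mer-m8": -0.4,
      "8mer": -0.6,
      "miRDB_only": -0.4,
      "validated": -0.5
    },
    "beta_jitter": [
      0.5,
      1.5
    ],
    "dispersion": 0.1,
    "fp_prediction_rate": 0.01,
    "frac_true_pairs": 0.1,
    "gamma_host": 1.0,
    "libsize_meanlog": 16.11809565095832,
    "libsize_sdlog": 0.3,
    "n_intragenic": 6,
    "n_mirna": 30,
    "n_mrna": 400,
    "n_samples": 40,
    "noise_sd": 1.0,
    "seed": 35627,
    "transfection_dispersion": 0.05,
    "transfection_noise_sd": 0.25
  },
  "concordance": {
    "mean_logFC_higher": -1.3006660845672946,
    "mean_logFC_lower": -1.51502293904792,
    "mirna_id": "miR-004",
    "n_higher_q20": 5,
    "n_lower_q20": 5,
    "p_one_sided": 0.16077902711890987,
    "t_stat": -1.0573869063649772
  },
  "correlation_census": {
    "mean_r_sig_neg": -0.5978719503957962,
    "mean_r_sig_pos": 0.5939848559660034,
    "n_pairs": 11970,
    "n_sig_neg": 67,
    "n_sig_pos": 7,
    "pct_sig_neg": 0.5597326649958229,
    "pct_sig_pos": 0.05847953216374269
  },
  "de_summary": {
    "asymmetry_chi2": 25.0,
    "asymmetry_p": 5.733031437583875e-07,
    "n_down": 25,
    "n_down_lfc": 25,
    "n_sig": 25,
    "n_up": 0,
    "n_up_lfc": 0
  },
  "decile_enrichment_vs_negative": {
    "chi2": 0.2440884820747521,
    "p": 0.6212686672172951,
    "table": [
      [
        13,
        27
      ],
      [
        10,
        30
      ]
    ]
  },
  "decile_enrichment_vs_random": {
    "chi2": 0.05952380952380952,
    "p": 0.8072501679320073,
    "table": [
      [
        13,
        27
      ],
      [
        11,
        29
      ]
    ]
  },
  "focus_mirna": "miR-004",
  "global_target_shift": [
    {
      "group": "mirdb",
      "ks_D": 0.742349937178292,
      "ks_p": 3.317126627204119e-11,
      "mean_shift": -0.2968024413659132,
      "n_nontarget": 4486,
      "n_target": 22
    },
    {
      "group": "targetscan",
      "ks_D": 0.43936984278958946,
      "ks_p": 1.3004425885660285e-48,
      "mean_shift": -0.2123984932758982,
      "n_nontarget": 4486,
      "n_target": 305
    }
  ],
  "locus_shift": {
    "ks_D": 0.9930033416875522,
    "ks_p": 5.246257629599209e-05,
    "mean_shift": 0.49651997956582583,
    "n_intergenic": 9576,
    "n_intragenic": 5
  },
  "mirlink_version": "0.1.0",
  "n_common_predicted_pairs": 13,
  "n_mirna_expressed": 30,
  "n_mrna_expressed": 399,
  "ora": {
    "mirdb": {
      "n_input": 214,
      "top_p_adj": 0.1369603612487205,
      "top_term": "TERM012"
    },
    "targetscan": {
      "n_input": 233,
      "top_p_adj": 0.4791542092868943,
      "top_term": "TERM005"
    }
  },
  "per_mirna_shift": [
    {
      "group": "8mer",
      "ks_D": 0.5652709359605912,
      "ks_p": 0.00018394702500921712,
      "mean_shift": -0.23540638204396686,
      "n_nontarget": 348,
      "n_target": 14
    },
    {
      "group": "7mer-m8",
      "ks_D": 0.6293103448275863,
      "ks_p": 0.00010226623128326694,
      "mean_shift": -0.3079895413695065,
      "n_nontarget": 348,
      "n_target": 12
    },
    {
      "group": "7mer-1a",
      "ks_D": 0.6408045977011494,
      "ks_p": 0.0003411432378226818,
      "mean_shift": -0.1829955736539902,
      "n_nontarget": 348,
      "n_target": 10
    },
    {
      "group": "mirdb",
      "ks_D": 0.5608519269776877,
      "ks_p": 3.4464057327332104e-09,
      "mean_shift": -0.254092032630885,
      "n_nontarget": 348,
      "n_target": 34
    },
    {
      "group": "mirtarbase",
      "ks_D": 0.8343782654127482,
      "ks_p": 3.56539806985894e-07,
      "mean_shift": -0.3207824980379216,
      "n_nontarget": 348,
      "n_target": 11
    }
  ],
  "seed": 35627,
  "thresholds": {
    "alpha_corr": 0.05,
    "alpha_de": 0.05,
    "context_general": -0.035,
    "context_go": -0.366,
    "lfc_cut": 1.0,
    "min_cpm": 1.0,
    "mirdb_go": 92.8,
    "mirdb_permirna": 85.0,
    "mirdb_top_fraction": 0.05,
    "q": 0.2,
    "r_go_max": -0.1,
    "top_mrna_fraction": 0.4,
    "transfection_delta": 1.0
  },
  "top_pairs": [
    "GENE074",
    "GENE010",
    "GENE335",
    "GENE051"
  ],
  "transfection_target_shift": [
    {
      "group": "8mer",
      "ks_D": 0.8284895620139172,
      "ks_p": 9.444551643762524e-09,
      "mean_shift": -1.0048900566478298,
      "n_nontarget": 349,
      "n_target": 14
    },
    {
      "group": "7mer-m8",
      "ks_D": 0.6351480420248328,
      "ks_p": 8.6093520163569e-05,
      "mean_shift": -0.8516415130051334,
      "n_nontarget": 349,
      "n_target": 12
    },
    {
      "group": "7mer-1a",
      "ks_D": 0.5452722063037249,
      "ks_p": 0.003086255592397329,
      "mean_shift": -0.38813930484317216,
      "n_nontarget": 349,
      "n_target": 10
    },
    {
      "group": "mirdb",
      "ks_D": 0.7454070453396258,
      "ks_p": 1.1161927562447322e-15,
      "mean_shift": -0.8680121546613427,
      "n_nontarget": 349,
      "n_target": 34
    },
    {
      "group": "mirtarbase",
      "ks_D": 0.8968481375358166,
      "ks_p": 3.5465271914509005e-08,
      "mean_shift": -1.308980009252887,
      "n_nontarget": 349,
      "n_target": 11
    }
  ]
}
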