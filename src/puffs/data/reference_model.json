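{
  "tpm": {
    "b": [9.513425, 1.312385, -0.448513, -0.581447, 1.775869, 0.007221],
    "std_errors": [1.332116, 0.594033, 0.05174, 0.101911, 0.149039, 0.000775],
    "t_stats": [7.14159, 2.209278, -8.668628, -5.705444, 11.915489, 9.321067],
    "p_values": [0.0, 0.028302, 0.0, 0.0, 0.0, 0.0],
    "q_range": [12.0, 65.0],
    "d_range": [1.0, 4.4],
    "diagnostics": {
      "r_squared": 0.905,
      "adj_r_squared": 0.903,
      "rmse_mg_ml": 0.012,
      "n_obs": 204,
      "n_params": 6
    }
  },
  "nic": {
    "beta": [0.009809, -5e-06],
    "std_errors": [0.001369, 5.5e-05],
    "t_stats": [7.167247, -0.08485],
    "p_values": [0.0, 0.028302],
    "diagnostics": {
      "r_squared": 0.0002,
      "rmse_mg_mg": 0.0025
    }
  },
  "meta": {
    "device": "NJOY vape-pen e-cigarette, no user-adjustable power",
    "e_liquid": "AVAIL Tobacco Row, labeled 1.8% nicotine, 50:50 PG/VG",
    "unpuffed_nicotine_mass_fraction_mg_mg": 0.014,
    "design": {
      "n_conditions": 34,
      "n_screening": 10,
      "reps_per_condition": 6,
      "n_trials": 204,
      "mean_session_volume_ml": 740.0,
      "session_volume_range_ml": [522.0, 1000.0]
    },
    "validation": {
      "n_sessions": 7,
      "reps_per_session": 6,
      "n_trials": 42,
      "tpm": {"m": 1.08, "r": 0.79, "r_squared": 0.58},
      "nic": {"m": 0.904, "r": 0.86, "r_squared": 0.71}
    },
    "units": {"q": "mL/s", "d": "s", "c_tpm": "mg/mL", "f_nic": "mg/mg"},
    "notes": "Coefficients are specific to this device/e-liquid pairing and are not transferable. The q/d envelope is the package's adopted natural-environment range; the original test envelope was reported graphically only."
  }
}
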