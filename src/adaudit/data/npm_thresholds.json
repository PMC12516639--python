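{
  "_provenance": "UK FSA/DHSC 2004-05 Nutrient Profiling Model technical guidance threshold tables, per-100 g basis. Band edges are strict (a value equal to a threshold scores in the lower band).",
  "a_points": {
    "energy_kj_per_100": [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350],
    "satfat_g_per_100": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
    "total_sugars_g_per_100": [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45],
    "sodium_mg_per_100": [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
  },
  "c_points": {
    "fvn_percent": {"thresholds": [40, 60, 80], "points": [1, 2, 5]},
    "fibre_nsp_g_per_100": [0.7, 1.4, 2.1, 2.8, 3.5],
    "fibre_aoac_g_per_100": [0.9, 1.8, 2.7, 3.6, 4.5],
    "protein_g_per_100": [1.6, 3.2, 4.8, 6.4, 8.0]
  },
  "protein_cap": {"a_points_at_least": 11, "unless_fvn_points_at_least": 5},
  "hfss_threshold": {"food": 4, "drink": 1}
}
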