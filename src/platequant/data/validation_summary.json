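{
  "description": "Published validation summary of the smartphone colorimetric protein assay: replicate RSDs (n=6) of the two validation samples, the detection limit from the two-fold dilution walk, spike recoveries, and the per-sample replicate SDs (g/100 g dry weight) of the ten-sample method comparison.",
  "replicate_rsd_percent": {"sample_4": 10.3, "sample_9": 10.9},
  "lod_ug_per_ml": 2.0,
  "twofold_series_ug_per_ml": [4.0, 2.0, 1.0, 0.5, 0.25],
  "recovery_percent": {"low_spike": 93.6, "high_spike": 92.3},
  "smartphone_sd_g_per_100g": [0.9, 0.4, 0.4, 0.5, 0.7, 0.7, 0.3, 0.7, 0.4, 0.9],
  "microplate_reader_sd_g_per_100g": [0.2, 0.0, 0.7, 0.2, 0.4, 0.1, 0.2, 0.4, 0.3, 0.0]
}
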