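# Demo run: synthetic audit at study scale, analysed at buffer 0 with the
# 5/10/20 m sensitivity ladder.
generator:
  seed: 1
  # expected asset count per deprivation quintile (Q1 = most deprived)
  asset_intensity: [74, 73, 50, 72, 26]
  hfss_fraction: 0.5
  brand_only_rate: 0.17
  missing_nutrition_rate: 0.15
buffers_m: [0, 5, 10, 20]
analysis_buffer_m: 0
out_dir: demo_out
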