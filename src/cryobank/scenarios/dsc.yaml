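name: dsc
kind: thermogram_set
params:
  reference_latent_heat: 335.0
  rates: [2.0, 4.0, 8.0, 16.0]
  ice_fractions: [1.0, 0.1, 0.01, 0.001]
analysis:
  threshold_pct: 0.5
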