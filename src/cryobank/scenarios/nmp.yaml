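name: nmp
kind: nmp
params:
  groups: [control, cold_24h, vmp, nanowarmed, vs55]
  n_kidneys: 4
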