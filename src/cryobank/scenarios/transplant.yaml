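name: transplant
kind: transplant
params:
  groups: [control, nanowarmed]
  n_animals: 5
  noise_scale: 1.0
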