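name: ct_vitrified
kind: ct_phantom
params:
  preset: vitrified_kidney
analysis:
  threshold_hu: 400.0
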