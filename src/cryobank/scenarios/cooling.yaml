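name: cooling
kind: temperature_log
params:
  rate: -20.5
  T_start: 0.0
  T_end: -150.0
  noise_sd: 0.5
analysis:
  critical_rate_C_min: 2.0
  window: [-128.3, -40.8]
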