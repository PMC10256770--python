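name: VMP loading
cpa: VMP
carrier: LM5-XZ
segments:
- kind: flush
  c_start: 0
  c_end: 0
  duration: 20
  pressure_setpoint: 40
  temperature: 4
- kind: ramp
  c_start: 0
  c_end: 5000
  rate: 50
  pressure_setpoint: 40
  temperature: 4
- kind: hold
  c_start: 5000
  c_end: 5000
  duration: 10
  pressure_setpoint: 40
  temperature: 4
- kind: step
  c_start: 8400
  c_end: 8400
  duration: 25
  pressure_setpoint: 60
  temperature: 4
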