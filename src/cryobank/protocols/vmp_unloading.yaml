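name: VMP unloading
cpa: VMP
carrier: LM5-XZ
segments:
- kind: hold
  c_start: 4200
  c_end: 4200
  duration: 15
  pressure_setpoint: 40
  temperature: 2
  adjunct:
    name: mannitol
    c_start: 300
    c_end: 300
- kind: ramp
  c_start: 4200
  c_end: 0
  rate: -35
  pressure_setpoint: 40
  temperature: 2
  adjunct:
    name: mannitol
    c_start: 300
    c_end: 0
    rate: -2.5
- kind: flush
  c_start: 0
  c_end: 0
  duration: 30
  pressure_setpoint: 40
  temperature: 2
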