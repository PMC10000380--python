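name: track_95
duration: 60.0
setpoint:
- - 0.0
  - 95.0
dt: 0.001
cylinder_tau: 0.5
condition: infected
input_delay: 0.0
intermediate_delay: 0.0
gas_model: canonical
controller:
  type: sfpimrac
  theta0: 0.0
  u_max: 200.0
  literal: false
  e_gain: 0.0013
  de_gain: 0.003
noise_std: 0.0
noise_seed: null
ref_drive: r
disturbance: null
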