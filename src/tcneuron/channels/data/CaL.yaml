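# High-threshold (L-type) calcium current: calcium influx during
# spiking, feeding the SK current through the intracellular calcium
# pool.  GHK conduction, m^2 alpha/beta kinetics from hippocampal
# voltage-clamp data (room temperature); Q10 = 3.  Editable defaults.
id: CaL
ion: Ca
conduction: {law: ghk, z: 2, cao: 2.0}
q10: 3.0
t_ref: 21.0
gates:
  - name: m
    exponent: 2
    form: alpha_beta
    params:
      alpha: {type: sigmoid, A: 1.6, V0: 5.0, B: 13.8888889}
      beta: {type: linexp, A: 0.02, V0: 1.31, B: 5.36}
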