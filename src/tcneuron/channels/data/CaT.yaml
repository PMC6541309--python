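# Low-threshold (T-type) calcium current: the generator of the
# low-threshold spike underlying burst firing.  GHK conduction with
# permeability, z = 2.  m^2 h kinetics from voltage-clamp data in young
# rat ventrobasal neurons (room temperature); editable defaults.
id: CaT
ion: Ca
conduction: {law: ghk, z: 2, cao: 2.0}
q10: 3.0
t_ref: 24.0
gates:
  - name: m
    exponent: 2
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -57.0, k: -6.2}
      tau: {type: recip2exp, c: 0.612, a1: -7.9041916, b1: -0.0598802,
            a2: 0.9230769, b2: 0.0549451}
  - name: h
    exponent: 1
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -81.0, k: 4.0}
      tau: {type: piecewise_exp, vsplit: -80.0, V1: -467.0, B1: 66.6,
            C: 28.0, V2: -22.0, B2: -10.5}
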