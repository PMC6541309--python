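# Fast transient (A-type) potassium current.  Two kinetic components
# (fast and slow), each with its own activation and inactivation
# variable; the current is the weighted sum
#   g * (0.6 m1^4 h1 + 0.4 m2^4 h2) (v - EK).
# Q10 = 2.8 (experimentally determined); kinetics recorded at room
# temperature in young rat ventrobasal neurons.  Editable defaults.
id: KA
ion: K
conduction: {law: ohmic, erev: ek}
q10: 2.8
t_ref: 23.0
terms:
  - {weight: 0.6, gates: {m1: 4, h1: 1}}
  - {weight: 0.4, gates: {m2: 4, h2: 1}}
gates:
  - name: m1
    exponent: 4
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -60.0, k: -8.5}
      tau: {type: recip2exp, c: 0.37, a1: 1.8172589, b1: 0.0507614,
            a2: -6.2755906, b2: -0.0787402}
  - name: h1
    exponent: 1
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -78.0, k: 6.0}
      tau: {type: recip2exp_capped, c: 0.0, a1: 9.2, b1: 0.2,
            a2: -6.3466667, b2: -0.0266667, vsplit: -63.0, cap: 19.0}
  - name: m2
    exponent: 4
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -36.0, k: -20.0}
      tau: {type: recip2exp, c: 0.37, a1: 1.8172589, b1: 0.0507614,
            a2: -6.2755906, b2: -0.0787402}
  - name: h2
    exponent: 1
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -78.0, k: 6.0}
      tau: {type: recip2exp_capped, c: 0.0, a1: 9.2, b1: 0.2,
            a2: -6.3466667, b2: -0.0266667, vsplit: -73.0, cap: 60.0}
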