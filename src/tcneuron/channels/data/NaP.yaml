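# Persistent sodium current: subthreshold depolarizing drive.
# Fast Boltzmann activation (half-activation -57.9 mV) with slow
# inactivation (half -58.7 mV).  The inactivation time constant is a
# constant slow default (5000 ms): the source's full voltage dependence
# is not reproduced here and this value is an editable best-effort
# placeholder.
id: NaP
ion: Na
conduction: {law: ohmic, erev: ena}
q10: 3.0
t_ref: 23.0
gates:
  - name: m
    exponent: 1
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -57.9, k: -6.4}
      tau: {type: constant, tau: 0.2}
  - name: h
    exponent: 1
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -58.7, k: 14.2}
      tau: {type: constant, tau: 5000.0}
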