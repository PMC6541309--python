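# Delayed-rectifier potassium current (spike repolarization).
# Traub-style n^4 kinetics, same model lineage and voltage shift as NaT.
# Constants are editable defaults.
id: Kd
ion: K
conduction: {law: ohmic, erev: ek}
q10: 3.0
t_ref: 36.0
gates:
  - name: n
    exponent: 4
    form: alpha_beta
    params:
      alpha: {type: linexp, A: -0.032, V0: -37.0, B: -5.0}
      beta: {type: exp, A: 0.5, V0: -42.0, B: -40.0}
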