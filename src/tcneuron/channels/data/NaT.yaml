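# Fast transient sodium current (action-potential upstroke).
# Traub-style alpha/beta kinetics from the classic rat thalamocortical
# relay model lineage; constants are editable defaults, transcribed with
# the original -52 mV activation shift folded into V0.
id: NaT
ion: Na
conduction: {law: ohmic, erev: ena}
q10: 3.0
t_ref: 36.0
gates:
  - name: m
    exponent: 3
    form: alpha_beta
    params:
      alpha: {type: linexp, A: -0.32, V0: -39.0, B: -4.0}
      beta: {type: linexp, A: 0.28, V0: -12.0, B: 5.0}
  - name: h
    exponent: 1
    form: alpha_beta
    params:
      alpha: {type: exp, A: 0.128, V0: -35.0, B: -18.0}
      beta: {type: sigmoid, A: 4.0, V0: -12.0, B: 5.0}
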