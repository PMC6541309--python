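# Small-conductance calcium-activated potassium current (spike-train
# adaptation).  Voltage-independent Hill activation of intracellular
# calcium (half-activation 0.00043 mM, Hill coefficient 4.8, from
# mRNA-expression data).  The gating time constant is set to 150 ms so
# the current tracks the slow calcium envelope of a spike train (the
# medium-AHP time scale) rather than single-spike transients; this is
# an editable functional default, not a measured value.
id: SK
ion: K
conduction: {law: ohmic, erev: ek}
q10: 1.0
t_ref: 34.0
gates:
  - name: z
    exponent: 1
    form: calcium_hill
    params:
      kd: 0.00043
      hill: 4.8
      tau: {type: constant, tau: 150.0}
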