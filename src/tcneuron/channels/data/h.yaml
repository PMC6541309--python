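# Hyperpolarization-activated cationic current (sag / rebound).
# Steady-state activation: Boltzmann with half-activation -86.4 mV and
# slope 11.2 mV (LJP-corrected); activation time constant
# 1/[exp(-14.59 - 0.086 v) + exp(-1.87 + 0.0701 v)].
# Ohmic with reversal -43 mV.  t_ref equals the default simulation
# temperature so the printed tau applies unscaled at 34 degC.
id: h
ion: nonspecific
conduction: {law: ohmic, erev: -43.0}
q10: 3.0
t_ref: 34.0
gates:
  - name: m
    exponent: 1
    form: inf_tau
    params:
      inf: {type: boltzmann, vhalf: -86.4, k: 11.2}
      tau: {type: recip2exp, c: 0.0, a1: -14.59, b1: -0.086,
            a2: -1.87, b2: 0.0701}
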