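# Voltage-insensitive leak current.  Reversal -79 mV: the average
# resting potential of the recorded population (LJP-corrected).
id: leak
ion: nonspecific
conduction: {law: ohmic, erev: -79.0}
q10: 1.0
t_ref: 34.0
gates: []
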