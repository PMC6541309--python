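# Frozen ground-truth parameter set, adapting e-type (cAD_ltb).
# Verified by simulation: tonic firing from -64 mV holding with
# adaptation index >= 0.029 (Step 200%), low-threshold burst with >= 2
# fast spikes from -84 mV holding (Step 125%), no spiking at rest or on
# either holding current.  Stronger SK/CaL and slow calcium decay give
# the adapting discharge.
etype: cAD_ltb
morphology_seed: 7
parameters:
  gNaT.s: 0.15
  gNaT.a: 0.20
  gKd.s: 0.08
  gKd.a: 0.10
  gNaP.s: 2.0e-6
  gNaP.d: 2.0e-6
  gKA.s: 0.02
  gKA.d: 0.01
  pCaT.sd: 7.0e-5
  pCaT.a: 1.0e-7
  pCaL.s: 1.0e-4
  pCaL.d: 1.0e-4
  gSK.s: 1.5e-4
  gSK.d: 1.5e-4
  gSK.a: 1.0e-7
  gh.s: 3.0e-6
  gh.d: 3.0e-6
  gleak.s: 3.0e-5
  gleak.d: 3.0e-5
  gleak.a: 3.0e-5
  gamma_Ca: 0.005
  tau_Ca: 250.0
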