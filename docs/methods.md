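# Methods

`tcneuron` builds, fits, validates and analyzes conductance-based models
of ventrobasal thalamocortical (TC) relay neurons — cells that fire in
two modes: regular *tonic* trains from a depolarized membrane potential
(holding target −64 mV) and *low-threshold bursts* — a slow T-type
calcium spike crowned by fast sodium spikes — from a hyperpolarized one
(−84 mV).  All voltages in the package are liquid-junction-potential
corrected values (−14 mV correction already applied); the uncorrected
experimental holding targets would read −50/−70 mV.

## Membrane mechanisms

Nine Hodgkin–Huxley-style mechanisms: fast sodium (NaT) and delayed
potassium (Kd) for the action potential, persistent sodium (NaP),
fast-transient A-type potassium (KA, two weighted kinetic components),
low-threshold T-type calcium (CaT), high-threshold L-type calcium
(CaL), calcium-activated SK potassium, the hyperpolarization-activated
cation current (h), and a leak with reversal −79 mV (the average
resting potential of the recorded population).  Calcium currents use
Goldman–Hodgkin–Katz conduction with permeabilities (z = 2, external
calcium 2 mM); all other currents are ohmic (E_Na 50 mV, E_K −90 mV).
The h-current kinetics are the printed curves: Boltzmann activation
with half-activation −86.4 mV, slope 11.2 mV, and
τ(v) = 1/[exp(−14.59 − 0.086 v) + exp(−1.87 + 0.0701 v)] ms.

Every mechanism is a declarative YAML file (gates, functional forms,
constants, conduction law, Q10 and reference temperature), interpreted
by a small library of named forms — no constant requires a code
change.  Kinetics not printed in the source literature are transcribed
best-effort from the classic thalamic-model lineages and flagged as
editable in the files.  Temperature scaling divides time constants by
q10^((T − T_ref)/10) and never touches steady states; KA carries
Q10 = 2.8 and CaL Q10 = 3.

Intracellular calcium is a single submembrane shell (depth 0.1 μm,
baseline 5e-5 mM) fed by the CaT and CaL currents with coupling
fraction γ_Ca and first-order decay τ_Ca; both are free parameters.
The SK gate is a voltage-independent Hill function of [Ca]i
(k_d 0.43 μM, Hill coefficient 4.8).  Its time constant is set to
150 ms so the current integrates the calcium envelope of a spike train
(the medium-AHP time scale) rather than tracking single-spike
transients; with an instantaneous SK gate the same conductance that
produces spike-frequency adaptation also clamps the low-threshold
spike and abolishes the burst crown, which contradicts the target
phenomenology.  This is a functional default, not a measured value,
and is editable like every other constant.

## Cell model and integration

Morphologies are section trees read from standard SWC.  Reconstructed
axons are replaced by a two-cylinder initial-segment stub (2 × 30 μm,
1 μm diameter).  Sections are split into ceil(L/40 μm) compartments;
membrane areas and axial resistances come from truncated-cone frusta
of the 3D points, so total area is conserved exactly under
re-discretization.  Global constants: 34 °C, 1 μF/cm², 100 Ω·cm,
v_init −79 mV.

The free-parameter vector has exactly 22 entries: per-region peak
conductances/permeabilities named `<param>.<region>` (".s" soma, ".d"
dendrites, ".a" axon) with the T-type permeability shared between soma
and dendrites (".sd"), plus γ_Ca and τ_Ca.  Default bounds are wide
(10⁻⁷–1 S/cm²); `search_bounds_for` applies per-channel physiological
ranges analogous to per-parameter initial ranges used when fitting
against recordings.

The integrator is a fixed-step theta method (Crank–Nicolson default,
dt = 0.025 ms) on the branched cable: ohmic and axial terms implicit,
solved per step by tree-ordered (Hines) elimination; gates advanced by
the exact exponential update at the current voltage (kinetics
tabulated on a 0.05 mV grid at the simulation temperature); GHK
currents explicit; calcium relaxed analytically toward its per-step
fixed point.  The inner loop is numba-compiled.  Correctness is
checked against closed-form RC responses, an independent adaptive-ODE
(LSODA) oracle on a three-compartment cell (< 0.05 mV), dt-halving
convergence, and section-order permutation invariance.  A fixed-step
scheme with convergence tests replaces the variable-step integrator
used in the original pipeline because it is reproducible bit-for-bit.

`single_compartment_reduction` collapses a cell to one isopotential
compartment with conserved total area and area-weighted densities — a
deliberate surrogate justified by the electrical compactness of TC
relay cells (dendritic extent ≪ length constant).  The synthetic
study (populations, fitting, sensitivity) runs on this surrogate; the
full cable model is used for the solver-correctness tests and is
available everywhere via `reduced=False`.  Cable filtering does shift
absolute tonic spike counts by tens of percent, which is why
morphology-swap evaluation (`me_combinations`) defaults to the same
reduction the targets were generated with.

## Stimuli (e-code)

All amplitudes are exact rational multiples of the rheobase I_thr.
Steps of 1350 ms at 50–300% in 25% increments (tonic and burst
holding variants), 270 ms threshold-ladder steps (50–130%, 4%),
3000 ms IV steps (−140–60%, 20%; the −140% and −40% steps constrain
sag and input resistance), three up-down ramp pairs to 300% (4000,
2000, 1250 ms), spontaneous-activity protocols, and an
Ornstein–Uhlenbeck noise stimulus.  Stimuli start 800 ms after
initialization.  Holding currents are found by bisection on the
steady-state somatic voltage (read as the mean of the last 100 ms of a
2 s injection, which smooths subthreshold ripple) to within 0.25 mV;
rheobase by coarse scan plus bisection to 1 pA on the 1350 ms step.
The OU sample uses the exact discretization (default τ = 3 ms,
σ = 0.5 relative units — the stimulus name encodes τ, the exact
values are not published) and replays bit-identically from its seed.
The noise scale w is the current at which the interpolated f–I curve
crosses 7.5 Hz.

## Features and targets

Spikes are upward crossings of −20 mV whose upstroke exceeds
20 mV/ms; the per-spike threshold voltage is where dV/dt first
exceeds that criterion, AP amplitude is peak minus threshold voltage,
AHP depth is measured relative to the voltage base.  The adaptation
index is the mean of (ISI_{i+1} − ISI_i)/(ISI_{i+1} + ISI_i) over
consecutive interspike intervals (≥ 3 spikes required); cells with
AI ≥ 0.029 on the 200% step are classified adapting (cAD_ltb), below
it non-adapting (cNAD_ltb), with the cutoff refit as the
equal-posterior point of a two-component Gaussian mixture when enough
values are available.  Undefined features are reported as `None` and
enter model ranking as a large finite penalty (250), keeping the
ranking total; models are ordered by worst (maximum) z-scored error,
ties by the sum.

## Synthetic data

The generator replaces the wet-lab recordings:

- **Morphologies** — random binary-branching trees calibrated to the
  measured anatomy: 3–7 trunks, radial extent 120–200 μm, first
  branch 20–50 μm from the soma, Sholl maximum 50–100 intersections
  at 50–80 μm, tapering diameters.  Branching depth is allocated per
  trunk to hit a target tip count, which is what the Sholl maximum
  measures.
- **Ground-truth e-models** — one frozen 22-parameter set per e-type,
  hand-tuned and then verified by simulation (the verification is the
  test suite): tonic firing at 150–250% threshold with AI on the
  correct side of 0.029, a ≥ 2-spike low-threshold burst at 125% from
  −84 mV, silence at rest and on both holdings.  They live on a
  compact reference morphology (≈ 24 tips) so full-cable runs stay
  fast; its extent and first-branch distance are inside the measured
  ranges.
- **Virtual populations** — log-normal jitter (SD 0.15) on all free
  parameters per cell; every virtual cell is re-normalized like an
  experimental one (holding searches, rheobase, battery scaled to its
  own threshold) before features are extracted (optionally with
  0.2 mV Gaussian measurement noise), and per-feature mean/STD tables
  are assembled with absolute STD floors per feature class.

What the population does *not* emulate: variability in channel
kinetics (voltage dependences are identical across virtual cells) and
experimental artifacts.  Because per-cell rheobase normalization
removes most density-driven variability too, the synthetic feature
STDs are several-fold tighter (≈ 3–5% of the mean for rate features)
than experimental across-cell distributions.  Passing tests therefore
certify pipeline correctness under tight, idealized targets — not
performance on real recordings.

## Fitting and validation

IBEA (additive-epsilon indicator, κ = 0.05) with blend-SBX crossover
and bounded polynomial mutation; order-of-magnitude parameters are
sampled log-uniformly and varied in log10 space.  Objective values
are min-max normalized with a 90th-percentile winsorized upper end so
failure penalties cannot erase selection pressure among viable
candidates.  Candidate evaluation re-normalizes the battery to the
candidate's own holding and rheobase currents, mirroring how every
cell behind the targets was normalized.  Full-scale profile:
100 × 100 × 3 seeds; scaled-down profile: 20 × 20 × 1 on the
reduction.  At the scaled-down budget (420 evaluations over a 12-D
log-scaled space against ten simultaneous objectives at the tight
synthetic STDs) the search is initialization-dominated: across many
measured runs the best worst-objective error typically lands between
3 and 5 STD and only occasionally below the 3-STD acceptance line, so
the end-to-end recovery test documents a guarantee that needs the
full-scale budget to hold reliably.

Generalization uses held-out stimuli: single ascending ramps (the
slow one in tonic mode, the fast one in burst mode) and the noise
stimulus, with targets taken from the reference model's own responses
(20% relative STD floor) — population-free, which keeps the
self-consistency contract exact.  Burst-mode ramp responses with more
than one burst event (≥ 2 spikes with ISIs < 30 ms per event) fail
the screen outright, regardless of feature errors.  Morphology-swap
testing re-runs both holding searches and the rheobase search per
morphology, rebuilds the battery, and selects the e-model with the
smallest maximum error (accepted below 3 STD).

## Sensitivity analysis

Elasticities by ±2.5% central differences of the baseline-normalized
feature (`S = 2` means a 3% parameter change moves the feature 6%);
zero-baseline features fall back to absolute differences and are
flagged; failed perturbed simulations leave entries missing, excluded
from norms.  Parameters rank by column 2-norm, features by row
2-norm; clustering uses the sign- and magnitude-blind angular
distance D = 1 − |cos θ| with average linkage.  On the bundled
non-adapting model the leak conductance is the most influential
membrane conductance (it sets the input resistance); the
calcium-coupling fraction γ_Ca rivals it overall through the
adaptation features.

## Morphology analysis

Sholl profiles count 3D sample segments straddling concentric spheres
(10 μm step).  The persistence barcode of the radial-distance
filtration assigns one (birth, death) bar per dendritic tip via
elder-rule merging at branch points; barcodes are rotation-invariant
and bar count equals tip count by construction.  Barcodes become
persistence images (Gaussian kernel, 100 × 100 grid over the padded
bounding box, bandwidth 5% of the maximum extent, unit mass) compared
with the normalized total-variation distance ½Σ|A − B|, which is a
metric bounded by [0, 1].  Sholl profiles are compared pairwise with
the k-sample Anderson–Darling test (p-values uncorrected, capped to
the tabulated range).

## Numerical choices and limitations

- Gate time constants are floored at 10⁻³ ms after temperature
  scaling.
- The voltage table spans −150 to +100 mV; simulations abort with a
  diagnostic if |v| exceeds 200 mV.
- Rank ties break by error sum, then stable input order.
- The two ground-truth e-types sit near the boundary between silence,
  tonic firing and rhythmic bursting that real TC cells also straddle;
  large parameter jitter can push a virtual cell into spontaneous
  oscillation, in which case it fails normalization and is resampled.
- Feature extraction assumes uniformly sampled traces.
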