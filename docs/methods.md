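# Methods

This note records the model as implemented: its assumptions, the parameter
choices that matter, the numerical methods, and what the package's tests do
and do not establish.

## Stimuli

Stimuli are length-versus-time traces (mm of displacement from resting
muscle length) on a uniform grid, default step 0.1 ms — fine enough to
resolve a 100 Hz vibration and the corners of ramp stretches. The default
protocol is a ramp-hold-release: 0.5 s baseline, 3 mm stretch at 20 mm/s,
1 s hold, release at the same speed, 0.3 s post. The 20 mm/s ramp is the
classical Ia identification velocity; amplitude and hold duration are
calibration choices (they are not uniquely determined by the in vivo
protocols the model emulates) and are config-overridable. Arbitrary recorded
kinematics can be supplied as two-column CSV (`t_s,length_mm`); non-uniform
grids are resampled by linear interpolation.

## Intrafusal mechanics

Each fibre is a single half-sarcomere. Two myosin states (detached/attached)
are resolved over a cross-bridge strain grid; two thin-filament states
(available/active) with nearest-neighbour cooperativity gate attachment.
Defaults: attachment scale f0 = 80 s⁻¹ confined to a Gaussian window
(σ = 2 nm) around zero strain; detachment g(x) = g0·(1+|x/4 nm|³) with
g0 = 12 s⁻¹ (strained bridges release fast — the source of the dynamic
force transient); thin-filament k_on = 60 s⁻¹·act, k_off = 40 s⁻¹,
cooperativity 4; activation fixed at 0.3 (no fusimotor drive). The chain
fibre runs the identical scheme with all rates ×6 ("fast" fibre); the bag
is the slow, dynamic fibre. Muscle stretch maps to half-sarcomere length
linearly (20 nm/mm); a linear length dependence of attachment
(0.8 %/nm) stands in for the ascending limb of the force-length relation so
maintained stretch sustains an elevated plateau force. Force units are
arbitrary; the transduction weights absorb the scale.

Numerics: strain grid ±10 nm at 161 bins. Filament sliding is applied as
exact whole-bin shifts plus an analytic sub-bin frame offset, so advection
adds no interpolation diffusion; attachment/detachment use a per-bin exact
exponential relaxation whose fixed point is dt-independent. Halving dt
changes the force trace by <0.5%; halving the bin width by <1%
(test-enforced).

## Transduction

The receptor potential is phenomenological: a non-negative conductance

g_drive = scale · (kfb·[F_bag]⁺ + kyb·[Y_bag]⁺ + kfc·[F_chain]⁺),

reversal 0 mV (generic cation), injected across the terminal compartments in
proportion to membrane area. The global scale is kept at its conventional
value 2×10⁵ (force→conductance conversion); the weights are the calibration
product (kfb = 8.83e-8, kyb = 2.52e-9, kfc = 4.56e-8 in force⁻¹·µS units)
and are held fixed for every experiment in the package. Because
mechanotransduction channels tile the terminal membrane, the *total*
injected conductance scales with terminal area when terminal length is
swept; per unit area the drive is invariant. Raw (unsubtracted) forces drive
the model, so the resting isometric force produces a tonic background
discharge — a normal Ia phenotype.

## Channel models

Rate constants are not measured quantities; they are model parameters chosen
to give each conductance its qualitative phenotype, then frozen. The
choices that matter:

* **Nav1.7** (6-state: C1-C2-C3-O-IF-IS): lowest activation midpoint
  (−50 mV), strong slow inactivation entered through the fast-inactivated
  state. It amplifies the slow receptor-potential depolarization and fires
  first, but fades under sustained depolarization — it cannot sustain tonic
  firing on its own.
* **Nav1.6** (10-state, two slow-inactivated states, one entered from the
  open and one from the fast-inactivated state): moderate threshold
  (−44 mV), deliberately weak slow inactivation. It is the isoform that
  keeps the repetitive (static-phase) pacemaker alive.
* **Nav1.1** (10-state, same topology): higher threshold (−40 mV), strong
  slow inactivation — a transient contributor to the onset/dynamic response.
* **Kv3.3**: high threshold (midpoint −25 mV on the squared gate), fast —
  spike repolarization that tolerates fast firing.
* **KCNQ**: non-inactivating, slow, midpoint −48 mV. Its subthreshold
  position makes it the brake that decides static-firing competence; with a
  more depolarized midpoint the static-failure phenomenon cannot occur
  inside the swept density range.
* **Kv1**: low-threshold delayed rectifier with slow partial inactivation,
  juxtaparanodal only.
* **SK2**: first-order activation by a Hill function (n = 2, half 0.25 µM)
  of a per-compartment Ca pool; medium-duration AHP and rate adaptation.

The Nav activation chain uses multiplicity-3:2:1 forward rates
α(V) = 2·exp((V−v_s)/12) ms⁻¹ (β symmetric), a closed-state inactivation
tier coupled by a fixed allosteric factor a = 3 (a modelling simplification;
it is not derived from microscopic reversibility), open-state fast
inactivation 0.6 ms⁻¹, and the slow-inactivation rates listed in
`channels.NAV_PARAMS`.

The Ca pool is a surrogate for an unmodelled high-voltage-activated Ca
source: influx at a fixed per-area gain, gated by a sigmoid of local voltage
(midpoint −25 mV) so it is spike-coupled, decaying to 0.05 µM with
τ = 50 ms. Coupling influx to the Na current instead (an alternative
surrogate) makes SK punish precisely the conductances that should promote
firing and inverts the Nav1.6 dependence of static firing; the voltage-gated
form avoids that artefact.

## Morphology and passive properties

Fixed topology: two terminal branches converge on one preterminal axon,
then heminode and four further nodes separated by myelinated internodes,
paranodes flanking each node. Base dimensions (all config-exposed; sweeps
are expressed as multipliers): terminal 240 µm × 1.5 µm per branch;
preterminal 20 µm × 0.7 µm; nodes/heminode 1.5 µm × 1.2 µm; paranodes
3 µm; internodes 100 µm with 50× reduced Cm and leak (myelin). Paranodes
sit under the myelin edge and carry partial attenuation (Cm 0.2 µF/cm²,
leak 1e-5 S/cm²). Cm = 1 µF/cm², Ra = 100 Ω·cm, leak 1e-4 S/cm² at
−65 mV elsewhere. The base terminal is a sizeable fraction of its DC space
constant: this is what makes 10-fold terminal *lengthening* nearly neutral
(added drive and added load cancel) while 10-fold *shortening* exposes the
fixed axonal load.

The printed density table distinguishes terminal / preterminal / heminode /
paranode. Ordinary nodes are not listed; they carry the heminode's Nav1.6 +
Kv3.3 complement at reduced Nav density (1200 pS/µm²) plus the KCNQ2/3
enrichment characteristic of mature nodes (0.05 S/cm²). Without that nodal
brake the distal node, being least loaded, becomes a tonic pacemaker under
the receptor-potential DC — which inverts the initiation order and masks
the terminal-conductance experiments.

## Numerics (cable model)

Backward Euler with Hines elimination on the compartment tree; dt =
0.0125 ms. Channel states advance first (HH gates by exact exponential,
Markov occupancies by a voltage-tabulated backward-Euler propagator,
linearly interpolated on a 0.2 mV grid and renormalized to the simplex);
the cable solve then treats all conductances implicitly. 500 ms of settling
at the initial drive precedes every analysed trace. Spike detection:
upward crossing of −20 mV, linearly interpolated, 1 ms refractory.

Accuracy: spike *counts* are dt-stable, and stimulus-locked spike times
converge to <0.1 ms under dt halving; free-running tonic spikes accumulate
phase drift (first-order splitting), so later absolute spike times are
compared via ISIs (<5% drift), not absolute times. Segment sizes are capped
at min(0.1 λ_DC, 20 µm) for unmyelinated regions.

## Feature windows

Initial burst: max instantaneous rate within 100 ms of ramp onset. Peak
dynamic: max instantaneous rate over the late ramp (after 30% of the ramp)
plus the first 20 ms of hold — measured separately from the onset burst
because the two quantities respond differently to perturbations and would
otherwise collapse into one number. Static average: mean instantaneous rate
over the middle 80% of the hold. All windows config-overridable; silent
windows yield a 0 with a flag ("static failure" marks the loss-of-static
phenotype). Features are measured at node 5 (the output toward the CNS).

## Calibration

`fit_base_model` minimizes mean relative feature error against a
prototypical target (defaults: burst 150 pps, peak dynamic 100, static 65)
over the transduction weights, with hard constraints burst > 100 pps and
peak dynamic > static > 0. The shipped defaults are the frozen result; all
experiments run against this single calibration, as the transduction weights
are meant to be fixed once and never retuned per experiment.

## What the experiments show (and known limitations)

With the frozen calibration the package reproduces, qualitatively and in
direction, every headline phenomenon it models: prototypical ramp response;
terminal-first AP initiation (terminal → heminode → node 5 for the first
five APs); terminal shortening reducing all three features while 10-fold
lengthening is weaker by an order of magnitude; preterminal elongation
attenuating the onset burst before a critical length at which dynamic
firing collapses and hold-phase firing turns irregular; static firing
abolished at high terminal KCNQ / zero Nav1.6 and restored by raising
Nav1.6, with the static-competence boundary crossed over a few pS/µm² of
Nav1.6 at fixed KCNQ.

Quantitatively, the sensitivities are larger than the corresponding in
vivo-fitted reference values by roughly 2–4×: the operating point sits in a
steep region of the drive→rate curve, so fractional-load changes are
amplified. The burst increase seen just *below* the preterminal collapse
threshold (before the collapse proper) reflects transient boosting by the
elongating, Nav-rich preterminal segment — a regime the model reports as
bi-stable/irregular via the hold-ISI CV flag. These magnitudes are
calibration-conditional; the acceptance script reports them as computed.

Not modelled: mechanotransduction channel biophysics (the generator is
phenomenological), fusimotor drive, autogenic feedback, within-region
density gradients, competitive occlusion between multiple pacemaker sites,
temperature dependence, and stochastic channel gating. The synthetic
stimulus generator emulates clean laboratory ramps and vibrations, not the
variability of natural movement; passing tests therefore establish internal
consistency and the stated phenomena under those protocols, not predictive
accuracy for arbitrary in vivo kinematics.
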