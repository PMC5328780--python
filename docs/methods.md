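# Methods

## Model equations

All units are nonspiking neurons with graded output
`s(V) = 1 / (1 + exp(−(V − θ_s)/σ_s))` (θ_s = −40 mV, σ_s = 3 mV) and
instantaneous graded synapses `I = g · s(V_pre) · (V_post − E_rev)`
(excitatory reversal 0 mV, inhibitory −80 mV).  CPG neurons are
two-variable relaxation units with a persistent inward current gated by a
slow inactivation variable h (sigmoidal m∞, h∞; τ_h(V) =
τ_h0 / cosh((V − θ_h)/2σ_h)); premotor interneurons, motoneurons and
sensory interneurons are single-variable leaky relays (τ = 10 ms).
Conductances are expressed in leak units (g_L = 1), times in ms.  The
committed cell parameters are in `src/stickwalk/data/baseline.yaml`; the
network graph (60 units, 60 synapses, 72 tonic drives) is assembled in
`stickwalk.leg` / `stickwalk.model` and integrated by a fixed-step RK4
kernel (numba) at dt = 0.1 ms, bit-reproducibly.

Muscles are first-order activation filters (τ_act = 25 ms) of motoneuron
output; each joint moves with velocity gain·(a_agonist − a_antagonist)
and is clamped exactly at its printed range (α 28–128°, β 30–60°,
γ 45–110°).  The gains (α 0.85, β 0.8, γ 0.45 deg/ms) set the swing
sweep times and are part of the committed calibration.

## Sensorimotor rules

The coxa-trochanter angle β is the load/ground-contact signal.  Per leg:

* **Gate latches.**  β rising through 33.8° (lift-off) selects
  protraction and the swing tibia program (extension; hind leg: flexion);
  β falling through 45° selects flexion (hind leg: extension) — the
  tibia switches earlier, at the higher threshold; β falling through 33°
  (ground contact) selects retraction.  Crossing direction encodes the
  sign of dβ, which debounces the thresholds; the 0.8° gap between the
  lift-off and touch-down latches prevents chatter when a leg rests at
  the ground threshold.  A fully elevated, protracting leg adopts the
  swing tibia posture even without a threshold crossing (the static
  complement of the lift-off rule).
* **Touch-down trigger.**  When α crosses the protraction-complete
  threshold (35°) a decaying pulse (τ = 40 ms) excites the depressor CPG
  neuron through a sensory interneuron: stance is initiated by position.
* **Load reflex.**  Low-pass-filtered ground contact (τ = 80 ms) weakly
  inhibits the levator CPG neuron (g = 0.05): load opposes swing
  initiation, so an uncoupled grounded leg stays grounded.
* **Swing-end reflex.**  An elevated (β ≥ 50°), fully protracted leg
  tonically excites its depressor CPG neuron (g = 0.15), so a swing
  always terminates even if the trigger pulse was missed.
* **Ground-proximity reflex.**  An unsupported leg below full elevation
  (33° < β < 50°) whose levator CPG neuron is silent has its levator
  motoneuron inhibited, so touch-down always completes.  Swing ascent,
  with the levator CPG active, is unaffected.

The last three rules are this model's operationalisation of the
position/load/velocity sensory sources of the network diagram.  Each was
added to remove a concrete spurious attractor found during the build
(mid-air "hover" fixed points of the balanced antagonistic motoneurons,
and a phase-locked mode in which the middle leg stepped in near-synchrony
with the hind leg); without them the gait analysis reports these states
as `unusual` patterns.

## Interleg coordination

The intersegmental pathways are inhibitory and caudo-rostral only:
HL β → ML LD pair (`g_inh9`), ML β → FL LD pair (`g_inh3`); the hind leg
receives none and is the rhythm source.  The instantaneous strength is
`g_max · σ((β_post − 45°)/2°) · r`, with r a slow synaptic resource
(weakly depressing; effectively constant at the committed time constants).
The levator branch is hyperpolarizing (−80 mV); the depressor branch is
*shunting* (reversal at rest, −65 mV), which silences the depressor
during the posterior swing without priming a post-inhibitory rebound —
at release the levator, whose slow variable was charged by the
hyperpolarization, therefore wins the restart race and the anterior leg
lifts one posterior-swing-duration after the leg behind it.

Coordination modes are pure drive sets (topology and mappings
unchanged).  Tetrapod uses weak LD drives (period ≈ 1186 ms, swing duty
≈ 0.22, lags ≈ 0.31/0.26 → lift-off order HL, ML, FL); tripod uses
strong drives (period ≈ 601 ms, duty ≈ 0.45, lags ≈ 0.55/0.52 → front
and hind leg in phase, middle leg anti-phase).  Segments differ in their
LD kinetics: the prothoracic pair is excitable only (deeper/faster
slow-variable setpoints), so the front leg steps solely on the
intersegmental release and rests grounded when uncoupled; the
mesothoracic levator recovers faster so the middle leg follows the short
tripod cycle one-for-one; the metathoracic pair free-runs.  This encodes
the functional asymmetry of the chain (hind leg as source, front leg
fully dependent) while keeping the three networks otherwise identical
copies.

## Calibration

The committed `baseline.yaml` was derived by deterministic drive sweeps
and bisection on the full model: hind/middle levator drives against the
target periods (tetrapod ≈ 1180 ms, tripod ≈ 615 ms; achieved 1186.4 and
601.2 ms, both within the ±5% calibration band), duty and lags against
the classifier templates, and the front-leg drive-decoupling command
(g_app3 ← 0.58 excitatory, g_app4 ← 0.10 inhibitory) at the boundary
where its two outcomes (permanent lift vs continued stepping) coexist
phase-dependently.  `stickwalk.experiments.calibrate` re-derives the
period calibration.  The period decreases monotonically with the levator
drive over the search interval but steeply near its lower end — the
committed values are therefore stated to four decimals.

Problem sizes used throughout (control runs 20 s, decoupling scenarios
22–30 s, sweeps of 24–25 onsets at 20 s each, dt = 0.1 ms) keep every
analysis window ≥ 8 full cycles past the transient; halving dt changes
the tetrapod period estimate by < 0.05%.

## What the synthetic gait fixtures do and do not show

`gait.make_fixture` produces square-wave β traces with prescribed period,
duty, lags and seeded Gaussian noise.  They exercise event detection,
debouncing, period/phase estimation and pattern classification completely
independently of the simulator — but they contain no transients, no
duty-cycle asymmetries between legs and no slow drift, so passing the
round-trip tests shows the *analysis* is correct, not that the simulator
produces such traces; that is what the control-run tests are for.

## Numerical choices

Fixed-step RK4 (dt = 0.1 ms default) with hard clamping of angles,
activations, h, pulses and resource variables after every step; gate
latches and trigger pulses update once per step from crossing detection
(event timing is therefore quantized at dt).  Command schedules are
applied exactly on step boundaries; runs are bit-reproducible and the
integrator aborts with the offending unit's name if any |V| exceeds
200 mV.  Event detection uses a 33° threshold with 1° hysteresis and
linear interpolation of crossing times; pattern classification uses
circular means of lift-off phases with 0.1-period tolerances; steady
postures require a 1° peak-to-peak band over the final seconds.

## Known limitations

Measured against the phenomenology this model family reports, the
following are not reproduced; the corresponding acceptance tests fail by
design rather than being weakened:

* **Tripod drive-decoupling window.**  The front-leg drive command
  succeeds at every tripod onset here (window = full period) instead of
  almost never (~50 ms).  Under the single release-chaining mechanism
  used for both modes, every per-event quantity (pulse duration,
  posterior swing length, protraction time) is nearly identical across
  modes — only the cycle cadence differs — so no slow process makes the
  tripod park fragile while keeping the tetrapod park stable.  A
  mode-specific coordination mechanism would be needed.
* **Hind-leg drive-removal bistability.**  Removing both hind-leg LD
  drives always ends grounded/retracted/stretched; the lifted outcome is
  erased because the position trigger and swing-end reflex reliably
  ignite even an undriven depressor.
* **Middle-leg decoupling side effects on the front leg.**  With the
  middle leg's β frozen at the ground, the front leg's pathway is silent
  and the (excitable) front leg parks grounded — the phase-dependent
  lifted / coordinated-stepping alternatives require front-leg dynamics
  beyond this architecture.  Likewise the slow (≈2×-period) middle-leg
  stepping after the tetrapod synapse-reversal manipulation is not
  reproduced.
* The success window of the tetrapod drive sweep is contiguous over 10 of
  24 onsets (494 ms) but flanked by two short failure bands rather than a
  single alternation, and starts ≈0.15 period after the hind-leg
  lift-off rather than at it.

The catalogue runner and the acceptance suite report these honestly; all
other panels of the decoupling catalogue (14 of 18) match their expected
outcomes.
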