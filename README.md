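# stickwalk

A neuromechanical model of three ipsilateral stick-insect legs — front
(FL), middle (ML) and hind (HL) — built to study how interleg coordination
survives when one leg is functionally *decoupled* from it.  The package is
for computational neuroscientists working on invertebrate locomotion: it
reproduces tripod and tetrapod coordination, the transition between them,
and a catalogue of leg-decoupling experiments (synaptic, central-drive and
premotor manipulations of each leg), with quantitative gait analysis of
every run.

## The model

Each leg carries three local control networks, one per joint:
protractor–retractor (PR, thorax–coxa angle α ∈ [28°, 128°]),
levator–depressor (LD, coxa–trochanter angle β ∈ [30°, 60°]; β encodes
elevation, load and ground contact) and extensor–flexor (EF, femur–tibia
supplementary angle γ ∈ [45°, 110°]).  Every network is a half-center CPG:
a pair of mutually inhibitory nonspiking neurons

    C dV/dt = −g_L (V − E_L) − g_P m∞(V) h (V − E_P) − Σ g s(V_pre)(V − E_rev)
    dh/dt   = (h∞(V) − h) / τ_h(V)

whose graded output s(V) drives motoneurons through inhibitory premotor
interneurons (`g_d` inputs), first-order muscle activations and
antagonistic joint velocities, hard-stopped at the anatomical ranges.
Intraleg coordination is sensory: β thresholds switch the PR and EF
systems between their stance and swing programs (the hind-leg tibia works
in anti-phase — it is *stretched* on the ground).

Interleg coordination runs caudo-rostrally through two inhibitory
intersegmental pathways onto the anterior LD CPGs (`g_inh9`: HL β → ML
pair C9/C10; `g_inh3`: ML β → FL pair C3/C4).  While the posterior leg
swings, the anterior pair is suppressed; at posterior touch-down the
release triggers a rebound of the anterior levator, chaining the
lift-offs.  The hind leg — the only leg without such input — is the
rhythm source.  Tripod and tetrapod differ only in the tonic drive sets
`g_app` to the LD CPGs, never in topology.

Decoupling a leg means, reversibly: (1) overriding its intersegmental
synapse (excitatory or blocked), (2) changing its LD central drives, or
(3) dis-/inhibiting its LD premotor interneurons.  Mechanism 2 is
phase-dependent — the same permanent command succeeds in one part of the
stepping cycle and fails in the complementary part; mechanism 3 works at
every phase.

## Worked example

```sh
python examples/control_gaits.py
```

prints, for the committed calibrated configuration:

```
tetrapod:
  classified pattern : tetrapod
  HL period        :  1186.5 ms (CV 0.04%)
  phase ML-HL      : 0.311 of a cycle
  phase FL-ML      : 0.261 of a cycle

tripod:
  classified pattern : tripod
  HL period        :   601.2 ms (CV 0.06%)
  phase FL-HL      : 0.072 of a cycle
  phase ML-HL      : 0.551 of a cycle
```

i.e. a ≈1186 ms tetrapod cycle with lift-off order HL → ML → FL at
≈1/3-period lags, and a ≈601 ms tripod cycle with front and hind leg in
phase and the middle leg in anti-phase.  `examples/decouple_front_leg.py`
shows the three decoupling mechanisms parking the front leg in its two
complementary rest postures while ML and HL keep stepping, and
`examples/phase_window_sweep.py` maps the phase-dependence of the drive
mechanism (a 494 ms contiguous success window of the 1186 ms period,
locked to the hind-leg lift-off).

The experiment catalogue (all decoupling panels) runs from the shell:

```sh
stickwalk catalogue --out runs/
stickwalk simulate --mode tripod --t-span 20000 --out tripod.csv
```

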