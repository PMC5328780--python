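"""Decoupling the front leg by each of the three mechanisms.

Applies, in separate 22 s tetrapod runs, (1) a permanent excitatory
override of the intersegmental synapse onto the front leg's levator CPG
neuron, (2) a block of the same synapse, and (3) the premotor-interneuron
manipulation, then prints the front leg's final state and confirms the
middle and hind leg keep stepping.  The synapse overrides park the leg
lifted/protracted/extended or grounded/retracted/flexed (the two
complementary rest postures); the premotor route parks it lifted at any
onset phase.
"""

from stickwalk import build_model
from stickwalk.decoupling import (DecouplingCommand, build_commands,
                                  classify_outcome)

cases = [
    ("synapse made excitatory",
     DecouplingCommand("intersegmental_synapse", "FL", "make_excitatory", 8000.0)),
    ("synapse blocked (g_inh3 = 0)",
     DecouplingCommand("intersegmental_synapse", "FL", "block", 8000.0)),
    ("premotor INs (depressor disinhibited, levator inhibited)",
     DecouplingCommand("premotor_in", "FL", "lift", 8000.0)),
]

for name, dc in cases:
    model = build_model(mode="tetrapod")
    traj = model.run(22000.0, build_commands(model, dc), record_dt=2.0)
    print(f"{name}:")
    print(f"  front leg outcome  : {classify_outcome(traj, 'FL', 8000.0)}")
    for leg in ("ML", "HL"):
        n = sum(1 for e in traj.events(leg)
                if e.kind == "liftoff" and e.t > 10000.0)
        print(f"  {leg} keeps stepping  : {n} further lift-offs")
    print()
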