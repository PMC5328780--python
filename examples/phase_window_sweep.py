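"""Phase dependence of the front-leg CPG-drive decoupling.

The same permanent drive change (excite the levator CPG neuron C3,
inhibit the depressor C4) either parks the front leg lifted or leaves its
stepping intact, depending on where in the stepping cycle the command
arrives.  This sweep applies the command at 12 onsets locked to a
hind-leg lift-off and prints the outcome per onset phase and the length
of the contiguous success window (S = leg parks lifted, f = stepping
continues).
"""

from stickwalk import ModelConfig
from stickwalk.decoupling import DecouplingCommand, sweep_command_phase

cfg = ModelConfig.default()
sweep = sweep_command_phase(cfg, DecouplingCommand("cpg_drive", "FL", "lift"),
                            n_phases=12, mode="tetrapod")

print(f"period {sweep.period_ms:.0f} ms, onsets locked to a hind-leg "
      f"lift-off at t = {sweep.anchor_ms:.0f} ms")
for onset, outcome in zip(sweep.onsets_ms, sweep.outcomes):
    phase = (onset - sweep.anchor_ms) / sweep.period_ms
    tag = "S" if outcome == "lifted_protracted_extended" else "f"
    print(f"  onset at {phase:4.2f} of the cycle -> {tag}  ({outcome})")
print(f"contiguous success window: {sweep.success_window_ms:.0f} ms "
      f"({100 * sweep.success_window_ms / sweep.period_ms:.0f}% of the period)")
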