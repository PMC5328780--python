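"""Decoupling mechanisms: validation, outcomes, reversibility, dominance."""

import numpy as np
import pytest

from stickwalk import ModelConfig, build_model
from stickwalk.decoupling import (DecouplingCommand, DecouplingError,
                                  build_commands, classify_outcome,
                                  revert_edits, sweep_command_phase)
from stickwalk.gait import summarize_traces
from conftest import liftoffs


def run_with(cfg, mode, dc, t=22000.0):
    model = build_model(cfg, mode=mode)
    return model.run(t, build_commands(model, dc), record_dt=2.0)


# ---------------------------------------------------------------------------
# command validation

def test_intersegmental_mechanism_invalid_for_hind_leg():
    with pytest.raises(DecouplingError, match="hind leg"):
        DecouplingCommand("intersegmental_synapse", "HL", "block", 0.0)


def test_unknown_mechanism_and_variant_rejected(cfg):
    with pytest.raises(DecouplingError):
        DecouplingCommand("amputation", "FL", "x", 0.0)
    model = build_model(cfg)
    with pytest.raises(DecouplingError, match="variant"):
        build_commands(model, DecouplingCommand("premotor_in", "FL", "bogus", 0.0))


def test_cpg_drive_rejects_foreign_keys(cfg):
    model = build_model(cfg)
    with pytest.raises(DecouplingError, match="g_app9"):
        build_commands(model, DecouplingCommand(
            "cpg_drive", "FL", {"g_app9": (0.5, 0.0)}, 0.0))


def test_revert_edits_restore_baseline(cfg):
    model = build_model(cfg, mode="tetrapod")
    dc = DecouplingCommand("premotor_in", "FL", "lift", 0.0)
    edits = build_commands(model, dc)[0].edits
    for e in edits:
        model._apply_edit(e)
    for e in revert_edits(model, edits):
        model._apply_edit(e)
    g_d0 = cfg.require("drives")["g_d0"]
    for key in ("g_d_IN_FL_lev", "g_d_IN_FL_dep"):
        assert model.drv_par[model.drive_index[key], 0] == g_d0


# ---------------------------------------------------------------------------
# outcomes (representative scenarios; the full set lives in the catalogue
# and the acceptance suite)

def test_synapse_block_front_leg_rests_grounded(cfg):
    tr = run_with(cfg, "tetrapod",
                  DecouplingCommand("intersegmental_synapse", "FL", "block", 8000.0))
    assert classify_outcome(tr, "FL", 8000.0) == "grounded_retracted_flexed"
    # the two intact legs keep alternating stepping
    for leg in ("ML", "HL"):
        per = np.diff(liftoffs(tr, leg, skip_ms=10000.0))
        assert len(per) >= 5 and per.std() / per.mean() < 0.05


def test_premotor_lift_is_phase_independent(cfg):
    """The premotor route acts downstream of the CPG: it parks the front
    leg lifted at every tested onset phase."""
    sweep = sweep_command_phase(
        cfg, DecouplingCommand("premotor_in", "FL", "lift"),
        n_phases=4, mode="tetrapod")
    assert sweep.success_fraction == 1.0
    # success + failure windows tile the period within one grid step
    step = sweep.period_ms / sweep.n_phases
    total = sweep.success_window_ms + sweep.failure_window_ms
    assert abs(total - sweep.period_ms) <= step + 1e-9


def test_reversibility_restores_pattern_within_five_cycles(cfg):
    """Removing a decoupling command lets 3-leg coordination resume: the
    pre-command label returns within 5 cycles of the offset."""
    model = build_model(cfg, mode="tripod")
    dc = DecouplingCommand("premotor_in", "FL", "lift", 8000.0,
                           offset_time=14000.0)
    T = 601.0
    tr = model.run(14000.0 + 7 * T + 4000.0, build_commands(model, dc),
                   record_dt=2.0)
    mask = tr.t >= 14000.0 + 2 * T
    s = summarize_traces(tr.t[mask], {g: tr.beta(g)[mask]
                                      for g in ("FL", "ML", "HL")})
    assert s.pattern == "tripod"


def test_rhythm_takeover_after_hind_leg_decoupling(cfg):
    """With the hind leg parked on the ground by the premotor route, the
    middle leg's LD network takes over as rhythm source: FL and ML keep
    stepping with stable periods."""
    tr = run_with(cfg, "tripod",
                  DecouplingCommand("premotor_in", "HL", "ground", 6000.0),
                  t=32000.0)
    assert classify_outcome(tr, "HL", 6000.0) == "other:grounded_retracted_stretched"
    for leg in ("FL", "ML"):
        per = np.diff(liftoffs(tr, leg, skip_ms=10000.0))
        assert len(per) >= 10
        assert per.std() / per.mean() < 0.05


def test_dominance_of_intersegmental_over_drive_mechanism(cfg):
    """Mechanisms 1+2 applied together on the front leg produce remaining-leg
    kinematics within 1° RMS of mechanism 1 alone: the intersegmental
    synapse (much larger conductance) dominates the central drive."""
    dc1 = [DecouplingCommand("intersegmental_synapse", "FL",
                             "make_excitatory", 8000.0)]
    dc12 = dc1 + [DecouplingCommand("cpg_drive", "FL", "lift", 8000.0)]
    runs = []
    for dcs in (dc1, dc12):
        model = build_model(cfg, mode="tetrapod")
        cmds = []
        for d in dcs:
            cmds += build_commands(model, d)
        runs.append(model.run(22000.0, cmds, record_dt=2.0))
    a, b = runs
    mask = a.t >= a.t[-1] - 10000.0
    for leg in ("ML", "HL"):
        diff = a.angles(leg)[mask] - b.angles(leg)[mask]
        rms = np.sqrt((diff ** 2).mean())
        assert rms < 1.0, (leg, rms)


def test_anchored_onset_requires_anchor(cfg):
    model = build_model(cfg)
    dc = DecouplingCommand("premotor_in", "FL", "lift", ("HL_liftoff", 100.0))
    with pytest.raises(DecouplingError, match="anchor"):
        build_commands(model, dc)
    cmds = build_commands(model, dc, anchor_time=5000.0)
    assert cmds[0].t_ms == 5100.0
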