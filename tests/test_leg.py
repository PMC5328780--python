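"""Single-leg machinery: muscles, joints, gates, wiring."""

import math

import numpy as np
import pytest

from stickwalk import ModelConfig
from stickwalk.config import ConfigError
from stickwalk.leg import (C_NAMES, GateState, JointAngles, MusclePair,
                           SensorySignals, build_leg,
                           gate_conductance_overrides, intraleg_sensory_gate,
                           joint_update, muscle_update)


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig.default()


# ---------------------------------------------------------------------------
# muscles and joints

def test_muscle_step_response_closed_form():
    m = MusclePair("LD", tau_act=25.0)
    dt, T = 0.5, 100.0
    for _ in range(int(T / dt)):
        m = muscle_update(1.0, m, dt)
    assert m.a_agonist == pytest.approx(1 - math.exp(-T / 25.0), abs=1e-6)


def test_muscle_fixed_point_and_95pct_at_3tau():
    m = MusclePair("EF", a_agonist=0.4, tau_act=25.0)
    assert muscle_update(0.4, m, 1.0).a_agonist == pytest.approx(0.4)
    m = MusclePair("EF", tau_act=25.0)
    for _ in range(150):   # 3 tau at dt = 0.5
        m = muscle_update(1.0, m, 0.5)
    assert m.a_agonist == pytest.approx(0.95, abs=0.01)
    with pytest.raises(ValueError):
        muscle_update(1.5, m, 1.0)


def test_joint_balanced_antagonists_leave_angle():
    ang = JointAngles(alpha=80.0, beta=45.0, gamma=70.0)
    muscles = {j: MusclePair(j, a_agonist=0.7, a_antagonist=0.7)
               for j in ("PR", "LD", "EF")}
    out = joint_update(ang, muscles, dt=5.0)
    assert (out.alpha, out.beta, out.gamma) == (80.0, 45.0, 70.0)


def test_joint_clamps_exactly_at_printed_range():
    """Full levator activation raises β monotonically and saturates at
    exactly 60°; full depressor activation brings it back to exactly 30°."""
    ang = JointAngles(beta=30.0)
    up = {j: MusclePair(j) for j in ("PR", "LD", "EF")}
    up["LD"] = MusclePair("LD", a_agonist=1.0, gain=0.5)
    betas = []
    for _ in range(200):
        ang = joint_update(ang, up, dt=1.0)
        betas.append(ang.beta)
    assert np.all(np.diff(betas)[:50] > 0)
    assert ang.beta == 60.0
    down = dict(up)
    down["LD"] = MusclePair("LD", a_antagonist=1.0, gain=0.5)
    for _ in range(200):
        ang = joint_update(ang, down, dt=1.0)
    assert ang.beta == 30.0


def test_joint_angles_validation():
    with pytest.raises(ValueError, match="beta"):
        JointAngles(beta=75.0).validate()


# ---------------------------------------------------------------------------
# intraleg sensory rules

def test_flexion_engages_before_retraction_on_descent():
    """Descending β switches the EF system at the higher threshold (45°)
    strictly before the PR system switches at ground contact (33°)."""
    gates = GateState(pr="protract", ef="extend")
    order = []
    beta = 60.0
    while beta > 30.0:
        prev = beta
        beta -= 1.0
        gates = intraleg_sensory_gate(
            SensorySignals(beta=beta, dbeta=-1.0, gamma_pos=60.0),
            gates, prev_beta=prev)
        order.append((gates.ef, gates.pr))
    flex_at = order.index(("flex", "protract"))
    retract_at = order.index(("flex", "retract"))
    assert flex_at < retract_at


def test_liftoff_engages_protraction_and_extension():
    gates = GateState(pr="retract", ef="flex")
    gates = intraleg_sensory_gate(
        SensorySignals(beta=33.5, dbeta=+1.0, gamma_pos=60.0),
        gates, prev_beta=32.5)
    assert gates.pr == "protract" and gates.ef == "extend"


def test_hind_leg_tibia_gating_is_inverted():
    gates = intraleg_sensory_gate(
        SensorySignals(beta=33.5, dbeta=+1.0, gamma_pos=60.0),
        GateState(pr="retract", ef="extend"), prev_beta=32.5, hind_leg=True)
    assert gates.ef == "flex"          # hind leg flexes in swing
    gates = intraleg_sensory_gate(
        SensorySignals(beta=44.5, dbeta=-1.0, gamma_pos=60.0),
        gates, prev_beta=45.5, hind_leg=True)
    assert gates.ef == "extend"        # and extends (stretches) for stance


def test_ground_contact_semantics():
    assert SensorySignals(beta=31.0, dbeta=0.0, gamma_pos=60.0).ground_contact
    assert not SensorySignals(beta=50.0, dbeta=0.0, gamma_pos=60.0).ground_contact


def test_gate_conductance_routing():
    ov = gate_conductance_overrides(GateState(pr="retract", ef="flex"),
                                    "FL", g_gate=0.8)
    assert ov["g_gate_C2"] == 0.8 and ov["g_gate_C1"] == 0.0
    assert ov["g_gate_C6"] == 0.8 and ov["g_gate_C5"] == 0.0


# ---------------------------------------------------------------------------
# wiring

def test_build_leg_structure(cfg):
    leg = build_leg("meta", cfg)
    assert leg.leg == "HL" and leg.segment == "meta"
    # exactly one PR, one LD, one EF CPG pair
    assert set(leg.cpg_pairs) == {"PR", "LD", "EF"}
    assert leg.cpg_pairs["LD"] == ("C15", "C16")
    kinds = {}
    for u in leg.units:
        kinds.setdefault(u.kind, []).append(u.id)
    assert len(kinds["cpg"]) == 6
    assert len(kinds["premotor_in"]) == 6
    assert len(kinds["motoneuron"]) == 6
    assert len(kinds["sensory_in"]) == 2


def test_premotor_motif(cfg):
    """Premotor INs inhibit their motoneurons and are excited by the
    antagonist CPG neuron; g_d drives are inhibitory, g_MN excitatory and
    uniform."""
    leg = build_leg("FL", cfg)
    syn = {(s.pre, s.post): s for s in leg.synapses}
    assert syn[("IN_FL_lev", "MN_FL_lev")].sign == "inhibitory"
    assert syn[("C4", "IN_FL_lev")].sign == "excitatory"   # depressor -> levator IN
    assert syn[("C3", "IN_FL_dep")].sign == "excitatory"
    g_mn = {leg.drives[i].g_app for k, i in leg.drive_addr.items()
            if k.startswith("g_MN_")}
    assert len(g_mn) == 1
    for k, i in leg.drive_addr.items():
        if k.startswith("g_d_"):
            assert leg.drives[i].E_rev == -80.0


def test_build_leg_missing_key_names_it(cfg):
    broken = cfg.copy()
    del broken.data["modes"]["tetrapod"]["g_app15"]
    with pytest.raises(ConfigError, match="g_app15"):
        build_leg("HL", broken)


def test_paper_neuron_numbering():
    assert C_NAMES["FL"] == ("C1", "C2", "C3", "C4", "C5", "C6")
    assert C_NAMES["ML"][2] == "C9"    # middle leg levator
    assert C_NAMES["HL"][3] == "C16"   # hind leg depressor
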