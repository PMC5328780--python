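"""Three-leg model: coordination patterns, invariants, determinism."""

import numpy as np
import pytest

from stickwalk import ModelConfig, build_model, intersegmental_strength
from stickwalk.config import ConfigError
from stickwalk.gait import summarize_traces
from stickwalk.model import Command, IntersegmentalSynapse, simulate_scenario
from conftest import liftoffs


def phases(traj, skip=4000.0):
    lo = {g: liftoffs(traj, g, skip) for g in ("FL", "ML", "HL")}
    out = {}
    for a, b in (("ML", "HL"), ("FL", "ML"), ("FL", "HL")):
        ph = []
        for ta in lo[a]:
            k = np.searchsorted(lo[b], ta) - 1
            if 0 <= k < len(lo[b]) - 1:
                ph.append((ta - lo[b][k]) / (lo[b][k + 1] - lo[b][k]))
        ang = 2 * np.pi * np.array(ph)
        out[f"{a}-{b}"] = float(np.mod(
            np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi), 1))
    return out


def circdist(a, b):
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


# ---------------------------------------------------------------------------

def test_tetrapod_control_pattern(tetrapod_traj):
    """Baseline tetrapod: lift-off order HL, ML, FL with ≈1/3-period lags."""
    s = tetrapod_traj.summarize()
    assert s.pattern == "tetrapod"
    ph = phases(tetrapod_traj)
    assert circdist(ph["ML-HL"], 1 / 3) < 0.1
    assert circdist(ph["FL-ML"], 1 / 3) < 0.1


def test_tripod_control_pattern(tripod_traj):
    """Baseline tripod: front and hind leg in phase, middle leg anti-phase."""
    s = tripod_traj.summarize()
    assert s.pattern == "tripod"
    ph = phases(tripod_traj)
    assert circdist(ph["FL-HL"], 0.0) < 0.1
    assert circdist(ph["ML-HL"], 0.5) < 0.1


def test_tetrapod_period_exceeds_tripod(tetrapod_period, tripod_period):
    assert tetrapod_period > tripod_period


def test_single_leg_rhythm_regularity(tetrapod_traj, tripod_traj):
    """Deterministic stepping: period CV < 1% for every leg in both modes."""
    for traj in (tetrapod_traj, tripod_traj):
        for leg in ("FL", "ML", "HL"):
            per = np.diff(liftoffs(traj, leg))
            assert per.std() / per.mean() < 0.01


def test_half_center_antiphase_in_all_pairs(tetrapod_traj):
    """No CPG pair has both outputs high more than 2% of the time after the
    transient."""
    pairs = [(f"C{6 * L + 1}", f"C{6 * L + 2}") for L in range(3)]
    pairs += [(f"C{6 * L + 3}", f"C{6 * L + 4}") for L in range(3)]
    pairs += [(f"C{6 * L + 5}", f"C{6 * L + 6}") for L in range(3)]
    post = tetrapod_traj.t > 2000.0
    for a, b in pairs:
        both = ((tetrapod_traj.output(a)[post] > 0.5)
                & (tetrapod_traj.output(b)[post] > 0.5))
        assert both.mean() < 0.02, (a, b)


def test_bounded_states(tetrapod_traj, tripod_traj):
    import stickwalk._kernel as K
    for traj in (tetrapod_traj, tripod_traj):
        V = traj.X[:, :K.NV]
        h = traj.X[:, K.OFF_H:K.OFF_H + K.NH]
        assert np.all(np.abs(V) < 200.0)
        assert np.all((h >= 0.0) & (h <= 1.0))


def test_angle_ranges_conserved(tetrapod_traj, tripod_traj):
    for traj in (tetrapod_traj, tripod_traj):
        for leg in ("FL", "ML", "HL"):
            ang = traj.angles(leg)
            assert ang[:, 0].min() >= 28.0 and ang[:, 0].max() <= 128.0
            assert ang[:, 1].min() >= 30.0 and ang[:, 1].max() <= 60.0
            assert ang[:, 2].min() >= 45.0 and ang[:, 2].max() <= 110.0


def test_bitwise_determinism(cfg):
    m1 = build_model(cfg)
    m2 = build_model(cfg)
    a = m1.run(4000.0)
    b = m2.run(4000.0)
    assert np.array_equal(a.X, b.X)


def test_dt_convergence_of_period(cfg):
    """Halving the step changes the tetrapod period estimate by < 0.5%,
    monotonically toward a limit."""
    def period(dt):
        m = build_model(cfg, mode="tetrapod")
        tr = m.run(14000.0, dt=dt)
        return np.diff(liftoffs(tr, "HL")).mean()

    t1, t2, t3 = period(0.4), period(0.2), period(0.1)
    assert abs(t2 - t1) / t1 < 0.005
    assert abs(t3 - t2) / t2 < 0.005
    assert abs(t3 - t2) <= abs(t2 - t1) + 1e-9


def test_mode_switch_preserves_topology_and_changes_label(cfg):
    m = build_model(cfg, mode="tripod")
    h0 = m.topology_hash()
    tr = m.run(26000.0, commands=[Command(11400.0, [("mode", "tetrapod")])])
    assert m.topology_hash() == h0
    mask = tr.t >= 11400.0 + 3 * 1186.0   # within ~3 tetrapod cycles
    s = summarize_traces(tr.t[mask], {g: tr.beta(g)[mask]
                                      for g in ("FL", "ML", "HL")})
    assert s.pattern == "tetrapod"


def test_intersegmental_strength_mapping(cfg):
    g_max = cfg.require("intersegmental")["g_inh3"]
    assert intersegmental_strength(30.0, cfg) < 0.01 * g_max
    assert intersegmental_strength(60.0, cfg) > 0.99 * g_max
    grid = [intersegmental_strength(b, cfg) for b in np.linspace(30, 60, 31)]
    assert np.all(np.diff(grid) >= 0)
    # fully depressed resource silences the pathway
    assert intersegmental_strength(60.0, cfg, r=0.0) == 0.0


def test_no_intersegmental_synapse_onto_hind_leg(cfg):
    with pytest.raises(ConfigError):
        IntersegmentalSynapse("ML", "HL", "g_bogus", 1.0)
    m = build_model(cfg)
    with pytest.raises(ConfigError):
        m._apply_edit(("intersegmental", "HL", 1, 0.0, -80.0))


def test_contradictory_commands_rejected(cfg):
    m = build_model(cfg)
    with pytest.raises(ValueError, match="contradictory"):
        simulate_scenario(m, 1000.0, [
            Command(500.0, [("drive", "g_app3", 0.5, 0.0)]),
            Command(500.0, [("drive", "g_app3", 0.1, 0.0)]),
        ])


def test_kinematics_frame_columns(tetrapod_traj):
    df = tetrapod_traj.kinematics_frame()
    assert list(df.columns)[0] == "t_ms"
    assert "HL_beta_deg" in df.columns and df.shape[1] == 10
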