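"""One leg: local control networks (PR, LD, EF), muscles, joints and the
intraleg sensory rules.

Each leg carries three local networks controlling its three joints:

* PR (protractor–retractor) — thorax–coxa angle α ∈ [28°, 128°]
  (28° maximal protraction, 128° maximal retraction),
* LD (levator–depressor) — coxa–trochanter angle β ∈ [30°, 60°]
  (30° on the ground, 60° maximal elevation),
* EF (extensor–flexor) — femur–tibia supplementary angle γ ∈ [45°, 110°]
  (45° maximal extension, 110° maximal flexion).

Every network is a CPG half-center pair feeding motoneurons through
inhibitory premotor interneurons; each motoneuron drives a first-order
muscle activation, and antagonistic activations move the joint at a
velocity proportional to their difference, hard-stopped at the anatomical
range.

Intraleg coordination is sensory: β encodes elevation, load and ground
contact.  When β falls below a threshold the leg is about to touch down,
which initiates stance (retraction); the same mechanism switches the EF
system to flexion earlier, at a *higher* β threshold.  On lift-off
(β rising through the ground threshold) the complementary protraction and
extension commands engage.  In the hind leg the tibia works in anti-phase
(it pushes by extending during stance), so its EF gating is inverted:
grounded means stretched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .config import ModelConfig, ConfigError
from .core import (E_EXC, E_INH, NeuronParams, NeuronUnit, Synapse,
                   TonicDrive, graded_output)

LEGS = ("FL", "ML", "HL")
SEGMENTS = {"FL": "pro", "ML": "meso", "HL": "meta"}
JOINTS = ("PR", "LD", "EF")
MUSCLES = ("pro", "ret", "lev", "dep", "ext", "flex")

#: paper-style numbering of the CPG neurons: C1..C6 prothoracic,
#: C7..C12 mesothoracic, C13..C18 metathoracic; within a segment the order
#: is PR pair, LD pair, EF pair (C3/C9/C15 are the levator neurons).
C_NAMES = {
    leg: tuple(f"C{6 * i + k + 1}" for k in range(6))
    for i, leg in enumerate(LEGS)
}

#: hind-leg LD premotor interneurons as named in the network diagram
PREMOTOR_ALIASES = {"IN_HL_dep": "IN29", "IN_HL_lev": "IN30"}


@dataclass
class JointAngles:
    """Joint angles of one leg, degrees, with the printed anatomical ranges."""
    alpha: float = 128.0
    beta: float = 30.0
    gamma: float = 110.0
    alpha_range: Tuple[float, float] = (28.0, 128.0)
    beta_range: Tuple[float, float] = (30.0, 60.0)
    gamma_range: Tuple[float, float] = (45.0, 110.0)

    def validate(self) -> None:
        for name, v, (lo, hi) in (("alpha", self.alpha, self.alpha_range),
                                  ("beta", self.beta, self.beta_range),
                                  ("gamma", self.gamma, self.gamma_range)):
            if not lo <= v <= hi:
                raise ValueError(f"{name} = {v} outside [{lo}, {hi}]")


@dataclass
class MusclePair:
    """Antagonistic muscle pair of one joint with first-order activations."""
    joint: str                     # PR | LD | EF
    a_agonist: float = 0.0         # activation in [0, 1]
    a_antagonist: float = 0.0
    tau_act: float = 25.0          # ms
    gain: float = 0.4              # deg/ms at full differential activation


@dataclass
class SensorySignals:
    """Sensory sources of one leg: β encodes position, load and ground
    contact; dβ encodes angular velocity; γ position is relayed likewise."""
    beta: float
    dbeta: float
    gamma_pos: float
    ground_threshold: float = 33.0

    @property
    def ground_contact(self) -> bool:
        return self.beta <= self.ground_threshold


@dataclass
class GateState:
    """Intraleg command latches: which side of the PR and EF systems the
    sensory rules currently excite."""
    pr: str = "retract"   # protract | retract
    ef: str = "flex"      # extend | flex


@dataclass
class LegState:
    """Complete wiring of one leg as unit/synapse/drive lists plus the
    mechanical state.  The drive table maps addressable symbols (g_app*,
    g_d*, g_MN per unit) to list indices so that experiments can override
    them."""
    leg: str
    segment: str
    units: List[NeuronUnit]
    synapses: List[Synapse]
    drives: List[TonicDrive]
    drive_addr: Dict[str, int]
    angles: JointAngles
    muscles: Dict[str, MusclePair]
    gates: GateState

    @property
    def cpg_pairs(self) -> Dict[str, Tuple[str, str]]:
        c = C_NAMES[self.leg]
        return {"PR": (c[0], c[1]), "LD": (c[2], c[3]), "EF": (c[4], c[5])}


def muscle_update(mn_output: float, muscle: MusclePair, dt: float,
                  antagonist_mn_output: float = 0.0) -> MusclePair:
    """One explicit integration step of the muscle activation pair,
    da/dt = (u - a)/tau_act (exact exponential update, unconditionally
    stable)."""
    if not 0.0 <= mn_output <= 1.0:
        raise ValueError("motoneuron output must lie in [0, 1]")
    decay = math.exp(-dt / muscle.tau_act)
    a_ag = mn_output + (muscle.a_agonist - mn_output) * decay
    a_an = antagonist_mn_output + (muscle.a_antagonist - antagonist_mn_output) * decay
    return replace(muscle, a_agonist=a_ag, a_antagonist=a_an)


def joint_update(angles: JointAngles, muscles: Dict[str, MusclePair],
                 dt: float) -> JointAngles:
    """Advance the three joint angles one step: dθ/dt = gain·(a_ag − a_ant),
    clamped to the printed ranges.  The LD agonist is the levator (raises β);
    the PR agonist is the retractor (raises α); the EF agonist is the flexor
    (raises γ)."""
    def step(theta, pair, rng):
        v = pair.gain * (pair.a_agonist - pair.a_antagonist)
        return min(max(theta + v * dt, rng[0]), rng[1])

    return replace(
        angles,
        alpha=step(angles.alpha, muscles["PR"], angles.alpha_range),
        beta=step(angles.beta, muscles["LD"], angles.beta_range),
        gamma=step(angles.gamma, muscles["EF"], angles.gamma_range),
    )


def intraleg_sensory_gate(signals: SensorySignals, gates: GateState,
                          *, beta_pr_thresh: float = 33.0,
                          beta_ef_thresh: float = 45.0,
                          prev_beta: Optional[float] = None,
                          hind_leg: bool = False) -> GateState:
    """Apply the β-threshold rules to the PR/EF command latches.

    Transitions are edge-triggered on β crossings with the matching sign of
    dβ (debounce): descending through the high threshold switches the EF
    system to flexion (hind leg: extension); descending through the ground
    threshold initiates retraction; ascending through the ground threshold
    (lift-off) engages protraction and extension (hind leg: flexion).
    ``prev_beta`` defaults to β − dβ (one unit step back).
    """
    b1 = signals.beta
    b0 = prev_beta if prev_beta is not None else b1 - signals.dbeta
    pr, ef = gates.pr, gates.ef
    if b0 < beta_pr_thresh <= b1 and signals.dbeta >= 0:
        pr = "protract"
        ef = "flex" if hind_leg else "extend"
    if b0 > beta_ef_thresh >= b1 and signals.dbeta <= 0:
        ef = "extend" if hind_leg else "flex"
    if b0 > beta_pr_thresh >= b1 and signals.dbeta <= 0:
        pr = "retract"
    return GateState(pr=pr, ef=ef)


def gate_conductance_overrides(gates: GateState, leg: str,
                               g_gate: float) -> Dict[str, float]:
    """Conductance overrides the current gate state routes into the PR and
    EF half-centers: an excitatory command conductance onto the selected
    CPG neuron of each pair (the mutual inhibition silences the other)."""
    c = C_NAMES[leg]
    out = {f"g_gate_{n}": 0.0 for n in (c[0], c[1], c[4], c[5])}
    out[f"g_gate_{c[0] if gates.pr == 'protract' else c[1]}"] = g_gate
    out[f"g_gate_{c[4] if gates.ef == 'extend' else c[5]}"] = g_gate
    return out


def _cpg_params(cfg: ModelConfig, pr_ef: bool, leg: str = "HL",
                role: str = "") -> NeuronParams:
    c = dict(cfg.require("neuron", "cpg"))
    if not pr_ef and leg == "FL":
        # prothoracic LD pair: excitable (non-pacemaker) regime — the front
        # leg steps only when the intersegmental release triggers a rebound.
        # The levator recovers fast (reliable 1:1 rebound at tripod cadence);
        # the depressor sits deeper so it never bursts spontaneously.
        c.update(cfg.get("neuron", "cpg_pro", default={}) or {})
        key = "cpg_pro_lev" if role == "lev" else "cpg_pro_dep"
        c.update(cfg.get("neuron", key, default={}) or {})
    if not pr_ef and leg == "ML":
        # mesothoracic levator: faster slow-variable recovery, so the middle
        # leg can follow the short tripod cycle one-for-one
        key = "cpg_meso_lev" if role == "lev" else "cpg_meso_dep"
        c.update(cfg.get("neuron", key, default={}) or {})
    if not pr_ef and leg == "HL":
        key = "cpg_meta_lev" if role == "lev" else "cpg_meta_dep"
        c.update(cfg.get("neuron", key, default={}) or {})
    out = cfg.require("neuron", "output")
    gP = cfg.require("neuron", "pr_ef_g_P") if pr_ef else c["g_P"]
    return NeuronParams(C=c["C"], g_L=c["g_L"], E_L=c["E_L"], g_P=gP,
                        E_P=c["E_P"], theta_m=c["theta_m"], sigma_m=c["sigma_m"],
                        theta_h=c["theta_h"], sigma_h=c["sigma_h"],
                        tau_h0=c["tau_h0"], theta_s=out["theta_s"],
                        sigma_s=out["sigma_s"])


def _passive_params(cfg: ModelConfig) -> NeuronParams:
    p = cfg.require("neuron", "passive")
    out = cfg.require("neuron", "output")
    return NeuronParams(C=p["C"], g_L=p["g_L"], E_L=p["E_L"], g_P=0.0,
                        theta_s=out["theta_s"], sigma_s=out["sigma_s"])


def build_leg(segment: str, cfg: ModelConfig) -> LegState:
    """Wire one leg from the configuration.

    Unit order (20): C_pro, C_ret, C_lev, C_dep, C_ext, C_flex, six premotor
    INs (same muscle order), six MNs, touch-down trigger IN, lift-off
    trigger IN.  Premotor INs are excited by the *antagonist* CPG neuron
    and inhibit their motoneuron, so each MN fires in phase with its own
    CPG neuron; disinhibiting a premotor IN (g_d → 0) silences its MN
    completely, inhibiting it frees the MN to fire tonically (g_MN).
    Raises :class:`~stickwalk.config.ConfigError` for missing keys.
    """
    leg = {v: k for k, v in SEGMENTS.items()}.get(segment, segment)
    if leg not in LEGS:
        raise ConfigError(f"unknown segment/leg: {segment!r}")
    hind = leg == "HL"

    cn = C_NAMES[leg]
    syn = cfg.require("synapses")
    drv = cfg.require("drives")
    E_inh = cfg.require("neuron", "E_inh")
    mode = cfg.mode
    ld_drives = cfg.mode_drives(mode)
    klev, kdep = {"FL": ("g_app3", "g_app4"), "ML": ("g_app9", "g_app10"),
                  "HL": ("g_app15", "g_app16")}[leg]

    cpg_lev = _cpg_params(cfg, pr_ef=False, leg=leg, role="lev")
    cpg_dep = _cpg_params(cfg, pr_ef=False, leg=leg, role="dep")
    cpg_pr_ef = _cpg_params(cfg, pr_ef=True)
    passive = _passive_params(cfg)

    units: List[NeuronUnit] = []
    for k, name in enumerate(cn):
        p = cpg_pr_ef if k not in (2, 3) else (cpg_lev if k == 2 else cpg_dep)
        units.append(NeuronUnit(name, "cpg", p))
    in_names = [f"IN_{leg}_{m}" for m in MUSCLES]
    mn_names = [f"MN_{leg}_{m}" for m in MUSCLES]
    units += [NeuronUnit(n, "premotor_in", passive) for n in in_names]
    units += [NeuronUnit(n, "motoneuron", passive) for n in mn_names]
    units += [NeuronUnit(f"SIN_{leg}_td", "sensory_in", passive),
              NeuronUnit(f"SIN_{leg}_lo", "sensory_in", passive)]

    synapses: List[Synapse] = []
    # mutual inhibition within each half-center; the LD pair's is weak so
    # that the levator can escape from the load-locked depressor
    for a, b in ((0, 1), (2, 3), (4, 5)):
        g_c = syn["g_c_ld"] if a == 2 else syn["g_c"]
        synapses.append(Synapse(cn[a], cn[b], g_c, E_inh))
        synapses.append(Synapse(cn[b], cn[a], g_c, E_inh))
    # CPG neuron -> premotor IN of the antagonist MN (excitatory)
    antagonist = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4}
    for k in range(6):
        synapses.append(Synapse(cn[k], in_names[antagonist[k]],
                                syn["g_ci"], E_EXC))
    # premotor IN -|> MN
    for k in range(6):
        synapses.append(Synapse(in_names[k], mn_names[k], syn["g_im"], E_inh))
    # sensory trigger INs -> LD CPG neurons
    synapses.append(Synapse(f"SIN_{leg}_td", cn[3], syn["g_td"], E_EXC))
    synapses.append(Synapse(f"SIN_{leg}_lo", cn[2], syn["g_lo"], E_EXC))

    drives: List[TonicDrive] = []
    drive_addr: Dict[str, int] = {}

    def add_drive(key, target, g, E):
        drive_addr[key] = len(drives)
        drives.append(TonicDrive(target, g, E))

    # central drives to the CPG neurons (PR/EF pairs are gate-driven; their
    # tonic g_app slots exist but are zero)
    idx0 = 6 * list(LEGS).index(leg)
    for k in range(6):
        key = f"g_app{idx0 + k + 1}"
        if k == 2:
            add_drive(key, cn[k], ld_drives[klev], E_EXC)
        elif k == 3:
            add_drive(key, cn[k], ld_drives[kdep], E_EXC)
        else:
            add_drive(key, cn[k], 0.0, E_EXC)
    # premotor INs: excitatory bias + individually variable inhibition g_d
    for k, n in enumerate(in_names):
        add_drive(f"g_b_{n}", n, drv["g_b"], E_EXC)
        add_drive(f"g_d_{n}", n, drv["g_d0"], E_inh)
    # uniform excitatory drive to all MNs
    for n in mn_names:
        add_drive(f"g_MN_{n}", n, drv["g_MN"], E_EXC)

    mus = cfg.require("muscles")
    gains = {"PR": mus["gain_alpha"], "LD": mus["gain_beta"],
             "EF": mus["gain_gamma"]}
    muscles = {j: MusclePair(j, tau_act=mus["tau_act_ms"], gain=gains[j])
               for j in JOINTS}
    ar = cfg.require("angles")
    angles = JointAngles(alpha=ar["alpha"][1], beta=ar["beta"][0],
                         gamma=ar["gamma"][0] if hind else ar["gamma"][1],
                         alpha_range=tuple(ar["alpha"]),
                         beta_range=tuple(ar["beta"]),
                         gamma_range=tuple(ar["gamma"]))
    gates = GateState(pr="retract", ef="extend" if hind else "flex")

    return LegState(leg=leg, segment=SEGMENTS[leg], units=units,
                    synapses=synapses, drives=drives, drive_addr=drive_addr,
                    angles=angles, muscles=muscles, gates=gates)
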