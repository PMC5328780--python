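"""The three-leg model: caudo-rostral coupling, modes, and simulation.

Three copies of the leg network sit in the pro-, meso- and metathoracic
segments (front, middle, hind leg).  Interleg coordination runs through two
inhibitory intersegmental synapses onto the levator CPG neurons of the LD
networks: ``g_inh3`` (onto C3, front leg) driven by the middle leg's β, and
``g_inh9`` (onto C9, middle leg) driven by the hind leg's β.  There is no
such synapse onto the hind leg's LD CPG — the hind leg is the source of the
rhythm, and activity propagates posterior → anterior: while the posterior
leg is in swing (β above the mapping threshold) the anterior levator neuron
is inhibited; at posterior touch-down the inhibition is released and the
anterior levator escapes (post-inhibitory rebound), so each leg lifts off
one posterior-swing-duration after the leg behind it.

Coordination *modes* differ only in the central drive sets to the LD CPGs
(never in topology): tripod drives are stronger (period ≈ 615 ms, swing
duty near 1/2 → hind and front leg in phase, middle leg in anti-phase),
tetrapod drives weaker (period ≈ 1180 ms, duty near 1/3 → lift-off order
HL, ML, FL with ≈1/3-period lags).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _kernel as K
from . import gait
from .config import ModelConfig, ConfigError, LD_DRIVE_KEYS, MODES
from .core import E_EXC, E_INH, NumericalBlowupError, graded_output
from .leg import LEGS, C_NAMES, GateState, LegState, build_leg

#: intersegmental override modes (kernel encoding)
IS_MODULATED, IS_CONSTANT = 0, 1


@dataclass(frozen=True)
class IntersegmentalSynapse:
    """Descriptor of one caudo-rostral coordinating synapse."""
    source_leg: str        # posterior leg whose β drives the strength
    target_leg: str        # anterior leg whose levator CPG neuron is hit
    symbol: str            # g_inh3 | g_inh9
    g_max: float
    E_rev: float = E_INH

    def __post_init__(self):
        if self.target_leg == "HL":
            raise ConfigError(
                "no intersegmental coordinating synapse targets the "
                "metathoracic (hind leg) LD CPG")


@dataclass(frozen=True)
class CoordinationMode:
    """A coordination pattern = a drive set over the six LD CPG neurons."""
    mode: str
    drives: Dict[str, float]


def intersegmental_strength(beta_posterior: float, cfg: ModelConfig,
                            mode: str = "tetrapod", r: float = 1.0) -> float:
    """Instantaneous strength of an intersegmental synapse.

    A sigmoid of the posterior leg's β around the mapping threshold (45° by
    default, steep enough to be effectively on/off), scaled by the slow
    synaptic resource ``r`` in [0, 1].  Memoryless given r; identical in
    both modes."""
    inter = cfg.require("intersegmental")
    g_max = inter["g_inh3"]
    act = 1.0 / (1.0 + np.exp(-(beta_posterior - inter["map_thr"])
                              / inter["map_slope"]))
    return float(g_max * act * np.clip(r, 0.0, 1.0))


Edit = Tuple  # ('drive', key, g, E) | ('intersegmental', leg, mode, g, E) | ('mode', name)


@dataclass
class Command:
    """A scheduled parameter override applied between integration steps."""
    t_ms: float
    edits: List[Edit]
    label: str = ""


@dataclass
class Trajectory:
    """Sampled state trajectory of a three-leg run."""
    t: np.ndarray                  # ms
    X: np.ndarray                  # (n, NX)
    model: "ThreeLegModel"
    command_log: List[Tuple[float, str]] = field(default_factory=list)

    def _leg_index(self, leg: str) -> int:
        return list(LEGS).index(leg)

    def angles(self, leg: str) -> np.ndarray:
        """(n, 3) array of (α, β, γ) in degrees."""
        L = self._leg_index(leg)
        return self.X[:, K.OFF_TH + 3 * L: K.OFF_TH + 3 * L + 3]

    def alpha(self, leg: str) -> np.ndarray:
        return self.angles(leg)[:, 0]

    def beta(self, leg: str) -> np.ndarray:
        return self.angles(leg)[:, 1]

    def gamma(self, leg: str) -> np.ndarray:
        return self.angles(leg)[:, 2]

    def V(self, unit_id: str) -> np.ndarray:
        return self.X[:, self.model.unit_index[unit_id]]

    def output(self, unit_id: str) -> np.ndarray:
        out = self.model.config.require("neuron", "output")
        return graded_output(self.V(unit_id), out["theta_s"], out["sigma_s"])

    def h(self, unit_id: str) -> np.ndarray:
        slot = self.model.h_slot[self.model.unit_index[unit_id]]
        if slot < 0:
            raise KeyError(f"{unit_id} has no slow variable")
        return self.X[:, K.OFF_H + slot]

    def events(self, leg: str, **kw):
        return gait.detect_events(self.t, self.beta(leg), leg=leg, **kw)

    def summarize(self, skip_ms: float = 3000.0, **kw) -> gait.GaitSummary:
        mask = self.t >= skip_ms
        t = self.t[mask]
        return gait.summarize_traces(
            t, {leg: self.beta(leg)[mask] for leg in LEGS},
            {leg: self.angles(leg)[mask] for leg in LEGS}, **kw)

    def kinematics_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t}
        for leg in LEGS:
            ang = self.angles(leg)
            cols[f"{leg}_alpha_deg"] = ang[:, 0]
            cols[f"{leg}_beta_deg"] = ang[:, 1]
            cols[f"{leg}_gamma_deg"] = ang[:, 2]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.kinematics_frame().to_csv(path, index=False)

    def state_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t}
        for uid, i in self.model.unit_index.items():
            cols[f"V_{uid}"] = self.X[:, i]
        return pd.DataFrame(cols)

    def final_state(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.X[-1].copy(), self.model._gate_pr.copy(),
                self.model._gate_ef.copy())


class ThreeLegModel:
    """Compiled three-leg network; deterministic fixed-step simulation."""

    def __init__(self, cfg: ModelConfig):
        self.config = cfg
        self.legs: Dict[str, LegState] = {leg: build_leg(leg, cfg)
                                          for leg in LEGS}
        inter = cfg.require("intersegmental")
        self.intersegmental = (
            IntersegmentalSynapse("ML", "FL", "g_inh3", inter["g_inh3"]),
            IntersegmentalSynapse("HL", "ML", "g_inh9", inter["g_inh9"]),
        )
        self._compile()
        self.reset()

    # ------------------------------------------------------------------
    def _compile(self) -> None:
        cfg = self.config
        self.unit_index: Dict[str, int] = {}
        nrn = np.zeros((K.NV, 10))
        h_slot = np.full(K.NV, -1, dtype=np.int64)
        syn_rows = []
        drv_rows = []
        drv_post = []
        self.drive_index: Dict[str, int] = {}

        nh = 0
        for L, leg in enumerate(LEGS):
            state = self.legs[leg]
            for k, u in enumerate(state.units):
                i = K.NUNIT * L + k
                self.unit_index[u.id] = i
                p = u.params
                nrn[i] = (p.C, p.g_L, p.E_L, p.g_P, p.E_P, p.theta_m,
                          p.sigma_m, p.theta_h, p.sigma_h, p.tau_h0)
                if p.g_P > 0:
                    h_slot[i] = nh
                    nh += 1
        for leg in LEGS:
            state = self.legs[leg]
            for s in state.synapses:
                syn_rows.append((self.unit_index[s.pre], self.unit_index[s.post],
                                 s.g, s.E_rev))
            for key, j in state.drive_addr.items():
                d = state.drives[j]
                self.drive_index[key] = len(drv_rows)
                drv_post.append(self.unit_index[d.target])
                drv_rows.append((d.g_app, d.E_rev))

        self.nrn = nrn
        self.h_slot = h_slot
        self.syn_idx = np.array([(a, b) for a, b, _, _ in syn_rows], dtype=np.int64)
        self.syn_par = np.array([(g, E) for _, _, g, E in syn_rows])
        self.drv_post = np.array(drv_post, dtype=np.int64)
        self.drv_par = np.array(drv_rows)
        self._drv_baseline = self.drv_par.copy()

        c = cfg.require("neuron", "cpg")
        out = cfg.require("neuron", "output")
        inter = cfg.require("intersegmental")
        gates = cfg.require("gates")
        sens = cfg.require("sensors")
        mus = cfg.require("muscles")
        ang = cfg.require("angles")
        P = np.zeros(K.NP_SCAL)
        P[K.P_THM], P[K.P_SGM] = c["theta_m"], c["sigma_m"]
        P[K.P_THH], P[K.P_SGH], P[K.P_TAUH0] = c["theta_h"], c["sigma_h"], c["tau_h0"]
        P[K.P_THS], P[K.P_SGS] = out["theta_s"], out["sigma_s"]
        P[K.P_EINH] = cfg.require("neuron", "E_inh")
        P[K.P_GGATE] = gates["g_gate"]
        P[K.P_THRPR], P[K.P_THREF] = gates["beta_pr_thresh"], gates["beta_ef_thresh"]
        P[K.P_MAPTHR], P[K.P_MAPSLOPE] = inter["map_thr"], inter["map_slope"]
        P[K.P_TAUREC], P[K.P_TAUDEP] = inter["tau_rec"], inter["tau_dep"]
        P[K.P_TAUPULSE], P[K.P_GPULSE] = sens["tau_pulse_ms"], sens["g_pulse"]
        P[K.P_TAUACT] = mus["tau_act_ms"]
        P[K.P_KALPHA], P[K.P_KBETA], P[K.P_KGAMMA] = (
            mus["gain_alpha"], mus["gain_beta"], mus["gain_gamma"])
        P[K.P_AMIN], P[K.P_AMAX] = ang["alpha"]
        P[K.P_BMIN], P[K.P_BMAX] = ang["beta"]
        P[K.P_GMIN], P[K.P_GMAX] = ang["gamma"]
        P[K.P_ATD], P[K.P_ALO] = sens["alpha_td_thresh"], sens["alpha_lo_thresh"]
        P[K.P_VSANITY] = 200.0
        load = cfg.require("load")
        P[K.P_TAULOAD], P[K.P_GLOAD] = load["tau_ms"], load["g_dep"]
        P[K.P_GLOADLEV] = load.get("g_lev", 0.0)
        P[K.P_GPARK] = sens.get("g_park", 0.0)
        P[K.P_BPARK] = sens.get("beta_park", 50.0)
        P[K.P_GGROUND] = sens.get("g_ground", 0.0)
        P[K.P_EDEP] = inter.get("E_dep", -65.0)
        P[K.P_GDEPF] = inter["g_dep_factor"]
        self.P = P

        g3 = inter["g_inh3"]
        g9 = inter["g_inh9"]
        E_inh = cfg.require("neuron", "E_inh")
        self._is_baseline = (
            np.array([IS_MODULATED, IS_MODULATED], dtype=np.int64),
            np.array([g3, g9], dtype=float),
            np.array([E_inh, E_inh], dtype=float),
        )

    # ------------------------------------------------------------------
    def topology_hash(self) -> str:
        """Hash of the synapse graph (indices + conductances + reversals).
        Mode switches must never change it."""
        m = hashlib.sha256()
        m.update(self.syn_idx.tobytes())
        m.update(self.syn_par.tobytes())
        m.update(self.drv_post.tobytes())
        return m.hexdigest()

    def reset(self, mode: Optional[str] = None) -> None:
        """Restore baseline parameters, set the mode, and build the
        deterministic initial state (all legs grounded in stance, hind leg
        primed to lift first)."""
        self.drv_par = self._drv_baseline.copy()
        self._is_mode, self._is_g, self._is_E = (
            self._is_baseline[0].copy(), self._is_baseline[1].copy(),
            self._is_baseline[2].copy())
        self.set_mode(mode or self.config.mode)

        EL = self.config.require("neuron", "cpg")["E_L"]
        X = np.zeros(K.NX)
        X[:K.NV] = EL
        X[K.OFF_H:K.OFF_H + K.NH] = 0.3
        gate_pr = np.empty(K.NLEG, dtype=np.int64)
        gate_ef = np.empty(K.NLEG, dtype=np.int64)
        # stagger the levator inactivation so the hind leg escapes first
        h_lev0 = {"FL": 0.30, "ML": 0.60, "HL": 0.95}
        for L, leg in enumerate(LEGS):
            base = K.NUNIT * L
            # stance-side units start active
            X[base + K.U_C_RET] = -40.0
            X[base + K.U_C_DEP] = -40.0
            X[base + (K.U_C_FLEX if leg != "HL" else K.U_C_EXT)] = -40.0
            X[K.OFF_H + self.h_slot[base + K.U_C_LEV]] = h_lev0[leg]
            X[K.OFF_H + self.h_slot[base + K.U_C_DEP]] = 0.25
            # muscle activations consistent with stance
            a = np.zeros(6)
            a[1] = a[3] = 1.0          # retractor, depressor
            a[5 if leg != "HL" else 4] = 1.0
            X[K.OFF_A + 6 * L: K.OFF_A + 6 * L + 6] = a
            jt = K.OFF_TH + 3 * L
            X[jt] = 128.0
            X[jt + 1] = 30.0
            X[jt + 2] = 45.0 if leg == "HL" else 110.0
            gate_pr[L] = 1
            gate_ef[L] = 0 if leg == "HL" else 1
        X[K.OFF_R:K.OFF_R + 2] = 1.0
        X[K.OFF_L:K.OFF_L + K.NLEG] = 1.0   # grounded, loaded
        self._X = X
        self._gate_pr = gate_pr
        self._gate_ef = gate_ef
        self._t = 0.0

    def set_mode(self, mode: str) -> None:
        drv = self.config.mode_drives(mode)
        for leg, (klev, kdep) in LD_DRIVE_KEYS.items():
            self.drv_par[self.drive_index[klev], 0] = drv[klev]
            self.drv_par[self.drive_index[kdep], 0] = drv[kdep]
            self.drv_par[self.drive_index[klev], 1] = E_EXC
            self.drv_par[self.drive_index[kdep], 1] = E_EXC
        self.mode = mode

    # ------------------------------------------------------------------
    def _apply_edit(self, edit: Edit) -> None:
        kind = edit[0]
        if kind == "drive":
            _, key, g, E = edit
            if key not in self.drive_index:
                raise ConfigError(f"unknown drive key: {key}")
            self.drv_par[self.drive_index[key], 0] = g
            self.drv_par[self.drive_index[key], 1] = E
        elif kind == "intersegmental":
            _, leg, mode, g, E = edit
            if leg not in ("FL", "ML"):
                raise ConfigError(
                    "no intersegmental coordinating synapse targets the "
                    "hind leg's LD CPG")
            L = 0 if leg == "FL" else 1
            self._is_mode[L] = mode
            self._is_g[L] = g
            self._is_E[L] = E
        elif kind == "mode":
            self.set_mode(edit[1])
        else:
            raise ValueError(f"unknown edit kind: {kind!r}")

    def baseline_drive(self, key: str) -> Tuple[float, float]:
        """Current-mode baseline (g, E) of a drive key, for reverts."""
        if key in self.drive_index:
            row = self._drv_baseline[self.drive_index[key]].copy()
            # mode table may have replaced the committed value
            for leg, keys in LD_DRIVE_KEYS.items():
                if key in keys:
                    return self.config.mode_drives(self.mode)[key], E_EXC
            return tuple(row)
        raise ConfigError(f"unknown drive key: {key}")

    def run(self, t_ms: float, commands: Sequence[Command] = (),
            record_dt: Optional[float] = None,
            dt: Optional[float] = None) -> Trajectory:
        """Integrate for ``t_ms`` applying scheduled commands.

        The trajectory continues from the model's current state; call
        :meth:`reset` for a fresh run.  Identical configurations and
        schedules give bit-identical trajectories.
        """
        dt = dt or self.config.get("sim", "dt_ms", default=0.1)
        record_dt = record_dt or self.config.get("sim", "record_dt_ms", default=1.0)
        if dt <= 0:
            raise ValueError("dt must be positive")
        stride = max(1, int(round(record_dt / dt)))
        n_steps = int(round(t_ms / dt))

        sched = sorted(commands, key=lambda c: c.t_ms)
        # contradictory same-time edits on one target are rejected
        seen: Dict[Tuple, Tuple] = {}
        for c in sched:
            for e in c.edits:
                tgt = (round(c.t_ms, 6), e[0], e[1])
                if tgt in seen and seen[tgt] != e:
                    raise ValueError(
                        f"contradictory commands at t={c.t_ms} ms on {e[1]}")
                seen[tgt] = e

        n_rec = n_steps // stride + 1
        rec = np.empty((n_rec, K.NX))
        rec[0] = self._X
        nrec = 1
        log: List[Tuple[float, str]] = []

        t0 = self._t
        step = 0
        bounds = [int(round((c.t_ms - t0) / dt)) for c in sched]
        for c, b in zip(sched, bounds):
            if b < 0 or b > n_steps:
                raise ValueError(f"command at t={c.t_ms} ms outside the run")
        ci = 0
        while step < n_steps:
            while ci < len(sched) and bounds[ci] <= step:
                for e in sched[ci].edits:
                    self._apply_edit(e)
                log.append((t0 + step * dt, sched[ci].label or str(sched[ci].edits)))
                ci += 1
            next_b = bounds[ci] if ci < len(sched) else n_steps
            seg = min(next_b, n_steps) - step
            if seg <= 0:
                seg = 1
            status, n = K.run_segment(
                self._X, self._gate_pr, self._gate_ef, self.nrn, self.h_slot,
                self.syn_idx, self.syn_par, self.drv_post, self.drv_par,
                self.P, self._is_mode, self._is_g, self._is_E,
                t0 + step * dt, dt, seg, stride, step, rec[nrec:])
            if status >= 0:
                uid = [k for k, v in self.unit_index.items() if v == status][0]
                raise NumericalBlowupError(uid, t0 + (step + n) * dt)
            nrec += n
            step += seg

        self._t = t0 + n_steps * dt
        t = t0 + np.arange(nrec) * (stride * dt)
        return Trajectory(t, rec[:nrec].copy(), self, log)


def build_model(cfg: Optional[ModelConfig] = None,
                mode: Optional[str] = None) -> ThreeLegModel:
    """Build the three-leg model from a configuration (default: the
    committed calibrated baseline)."""
    cfg = cfg or ModelConfig.default()
    if mode is not None:
        cfg = cfg.updated("mode", mode)
    return ThreeLegModel(cfg)


def simulate_scenario(model: ThreeLegModel, t_span_ms: float,
                      command_schedule: Sequence[Command] = (),
                      record_dt: Optional[float] = None) -> Trajectory:
    """Reset the model and run one scenario from t = 0."""
    model.reset()
    return model.run(t_span_ms, commands=command_schedule, record_dt=record_dt)
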