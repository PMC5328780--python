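"""Conductance-based nonspiking neuron units, graded synapses and RK4 integration.

Every unit in the walking network is a nonspiking neuron whose output is a
bounded sigmoid of its membrane potential.  Two unit kinds exist:

* **CPG neurons** — two-variable relaxation units with a persistent inward
  current gated by a slow inactivation variable h::

      C dV/dt = -g_L (V - E_L) - g_P m∞(V) h (V - E_P) - I_syn - I_drive
      dh/dt   = (h∞(V) - h) / τ_h(V)

  A mutually inhibitory pair of such units (a half-center) oscillates in
  anti-phase over a range of tonic drives, with the period set mainly by
  τ_h and the drive conductances.

* **passive units** — premotor interneurons, sensory interneurons and
  motoneurons are single-variable leaky relays (the g_P term absent).

Synaptic transmission is instantaneous and graded:
``I_syn = g · s(V_pre) · (V_post - E_rev)`` with the same output sigmoid
``s``.  Excitatory reversal is 0 mV, inhibitory reversal -80 mV, far below
the operating range.

This module provides the unit-level equations plus a small reference
integrator for arbitrary networks of such units; the full three-leg model
runs through the compiled kernel in :mod:`stickwalk._kernel`, which
implements the same equations on flat arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

E_EXC = 0.0     # mV, excitatory reversal
E_INH = -80.0   # mV, inhibitory reversal

#: sanity bound on membrane potentials; beyond this the integration aborts
V_SANITY = 200.0


class NumericalBlowupError(RuntimeError):
    """Integration produced a non-finite or absurd state."""

    def __init__(self, unit_id: str, t: float):
        super().__init__(f"numerical blow-up in unit '{unit_id}' at t = {t:.3f} ms")
        self.unit_id = unit_id
        self.t = t


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters of one unit.  Conductances in arbitrary units
    (leak = 1 defines the scale), capacitance in conductance·ms so that
    τ = C/g_L is in milliseconds."""
    C: float = 20.0
    g_L: float = 1.0
    E_L: float = -65.0
    # persistent inward current (CPG kind only; g_P = 0 for passive units)
    g_P: float = 0.0
    E_P: float = 40.0
    theta_m: float = -44.0
    sigma_m: float = 4.0
    theta_h: float = -55.0
    sigma_h: float = 4.0
    tau_h0: float = 2500.0
    # output sigmoid
    theta_s: float = -40.0
    sigma_s: float = 3.0


@dataclass(frozen=True)
class NeuronUnit:
    id: str
    kind: str  # {"cpg", "premotor_in", "sensory_in", "motoneuron"}
    params: NeuronParams = field(default_factory=NeuronParams)

    @property
    def is_cpg(self) -> bool:
        return self.kind == "cpg"


@dataclass
class NeuronState:
    V: float
    h: float = 1.0  # slow inactivation, CPG kind only


@dataclass(frozen=True)
class Synapse:
    pre: str
    post: str
    g: float
    E_rev: float

    def __post_init__(self):
        if self.g < 0:
            raise ValueError(f"synapse {self.pre}->{self.post}: g must be >= 0")

    @property
    def sign(self) -> str:
        return "excitatory" if self.E_rev >= -40.0 else "inhibitory"


@dataclass(frozen=True)
class TonicDrive:
    target: str
    g_app: float
    E_rev: float = E_EXC

    def __post_init__(self):
        if self.g_app < 0:
            raise ValueError(f"drive on {self.target}: g_app must be >= 0")


def graded_output(V, theta: float = -40.0, sigma: float = 3.0):
    """Monotone bounded sigmoid mapping membrane potential to [0, 1]."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - theta) / sigma))


def m_inf(V, theta, sigma):
    return 1.0 / (1.0 + np.exp(-(V - theta) / sigma))


def h_inf(V, theta, sigma):
    return 1.0 / (1.0 + np.exp((V - theta) / sigma))


def tau_h(V, theta, sigma, tau0):
    return tau0 / np.cosh((V - theta) / (2.0 * sigma))


def neuron_rhs(unit: NeuronUnit, state: NeuronState,
               total_synaptic_current: float, t: float = 0.0
               ) -> Tuple[float, float]:
    """Time derivatives (dV/dt, dh/dt) of one unit.

    ``total_synaptic_current`` is the summed outward synaptic + drive
    current g·s_pre·(V - E).  For passive units dh/dt is returned as 0.
    """
    p = unit.params
    V, h = state.V, state.h
    if not (math.isfinite(V) and math.isfinite(h)
            and math.isfinite(total_synaptic_current)):
        raise NumericalBlowupError(unit.id, t)
    I = p.g_L * (V - p.E_L) + total_synaptic_current
    dh = 0.0
    if unit.is_cpg and p.g_P > 0:
        I += p.g_P * m_inf(V, p.theta_m, p.sigma_m) * h * (V - p.E_P)
        dh = (h_inf(V, p.theta_h, p.sigma_h) - h) / tau_h(
            V, p.theta_h, p.sigma_h, p.tau_h0)
    return -I / p.C, dh


@dataclass
class Network:
    """A small explicit network of units, synapses and tonic drives."""
    units: List[NeuronUnit]
    synapses: List[Synapse] = field(default_factory=list)
    drives: List[TonicDrive] = field(default_factory=list)

    def __post_init__(self):
        self._index = {u.id: i for i, u in enumerate(self.units)}
        ids = set(self._index)
        for s in self.synapses:
            if s.pre not in ids or s.post not in ids:
                raise KeyError(f"synapse references unknown unit: {s.pre}->{s.post}")
        for d in self.drives:
            if d.target not in ids:
                raise KeyError(f"drive references unknown unit: {d.target}")

    def index(self, unit_id: str) -> int:
        return self._index[unit_id]


@dataclass
class StateTrajectory:
    """Uniformly sampled trajectory: t (ms) plus one column per variable."""
    t: np.ndarray
    V: np.ndarray              # (n_samples, n_units)
    h: np.ndarray              # (n_samples, n_units); 1 for passive units
    unit_ids: List[str]

    def output(self, unit_id: str, params: Optional[NeuronParams] = None
               ) -> np.ndarray:
        p = params or NeuronParams()
        j = self.unit_ids.index(unit_id)
        return graded_output(self.V[:, j], p.theta_s, p.sigma_s)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t}
        for j, uid in enumerate(self.unit_ids):
            cols[f"V_{uid}"] = self.V[:, j]
        for j, uid in enumerate(self.unit_ids):
            cols[f"h_{uid}"] = self.h[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _network_rhs(net: Network, V: np.ndarray, h: np.ndarray, t: float
                 ) -> Tuple[np.ndarray, np.ndarray]:
    n = len(net.units)
    I = np.zeros(n)
    s_pre = np.empty(n)
    for i, u in enumerate(net.units):
        p = u.params
        x = (V[i] - p.theta_s) / p.sigma_s
        s_pre[i] = 1.0 if x > 40 else (0.0 if x < -40
                                       else 1.0 / (1.0 + math.exp(-x)))
    for syn in net.synapses:
        i, j = net.index(syn.pre), net.index(syn.post)
        I[j] += syn.g * s_pre[i] * (V[j] - syn.E_rev)
    for d in net.drives:
        j = net.index(d.target)
        I[j] += d.g_app * (V[j] - d.E_rev)
    dV = np.empty(n)
    dh = np.zeros(n)
    for i, u in enumerate(net.units):
        dV[i], dh[i] = neuron_rhs(u, NeuronState(V[i], h[i]), I[i], t)
    return dV, dh


def integrate(net: Network, initial_state: Dict[str, NeuronState],
              t_span: Tuple[float, float], dt: float,
              event_hooks: Sequence[Callable[[float, Network], Optional[Network]]] = (),
              record_dt: Optional[float] = None) -> StateTrajectory:
    """Fixed-step RK4 integration of a unit network.

    ``event_hooks`` are pure functions of (t, network) called once per step
    before the step is taken; a hook may return a replacement Network (same
    units, possibly rewritten conductances) or None.  Integration is
    deterministic: identical inputs give bit-identical trajectories.

    Raises :class:`NumericalBlowupError` naming the first offending unit if
    any |V| exceeds the sanity bound.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0, t1 = t_span
    n_steps = int(round((t1 - t0) / dt))
    stride = max(1, int(round((record_dt or dt) / dt)))

    n = len(net.units)
    V = np.array([initial_state[u.id].V for u in net.units], dtype=float)
    h = np.array([initial_state[u.id].h for u in net.units], dtype=float)

    n_rec = n_steps // stride + 1
    rec_t = np.empty(n_rec)
    rec_V = np.empty((n_rec, n))
    rec_h = np.empty((n_rec, n))
    rec_t[0], rec_V[0], rec_h[0] = t0, V, h
    k = 1

    t = t0
    for step in range(n_steps):
        for hook in event_hooks:
            out = hook(t, net)
            if out is not None:
                net = out
        # classic RK4
        k1V, k1h = _network_rhs(net, V, h, t)
        k2V, k2h = _network_rhs(net, V + 0.5 * dt * k1V, h + 0.5 * dt * k1h, t + 0.5 * dt)
        k3V, k3h = _network_rhs(net, V + 0.5 * dt * k2V, h + 0.5 * dt * k2h, t + 0.5 * dt)
        k4V, k4h = _network_rhs(net, V + dt * k3V, h + dt * k3h, t + dt)
        V = V + (dt / 6.0) * (k1V + 2 * k2V + 2 * k3V + k4V)
        h = np.clip(h + (dt / 6.0) * (k1h + 2 * k2h + 2 * k3h + k4h), 0.0, 1.0)
        t = t0 + (step + 1) * dt
        bad = np.flatnonzero(~np.isfinite(V) | (np.abs(V) > V_SANITY))
        if bad.size:
            raise NumericalBlowupError(net.units[bad[0]].id, t)
        if (step + 1) % stride == 0:
            rec_t[k], rec_V[k], rec_h[k] = t, V, h
            k += 1

    return StateTrajectory(rec_t[:k], rec_V[:k], rec_h[:k],
                           [u.id for u in net.units])


def half_center(prefix: str, drive_a: float, drive_b: float,
                g_inh: float = 3.0, params: Optional[NeuronParams] = None
                ) -> Network:
    """Convenience constructor: a mutually inhibitory CPG pair with tonic
    excitatory drives — the elementary half-center oscillator."""
    p = params or NeuronParams(g_P=2.0)
    a, b = f"{prefix}1", f"{prefix}2"
    return Network(
        units=[NeuronUnit(a, "cpg", p), NeuronUnit(b, "cpg", p)],
        synapses=[Synapse(a, b, g_inh, E_INH), Synapse(b, a, g_inh, E_INH)],
        drives=[TonicDrive(a, drive_a, E_EXC), TonicDrive(b, drive_b, E_EXC)],
    )
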