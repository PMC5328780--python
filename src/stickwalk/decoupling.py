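"""The three leg-decoupling mechanisms, as scheduled reversible overrides.

A leg can be functionally decoupled from the interleg coordination by

1. **intersegmental_synapse** — perturbing the coordinating synapse onto
   its LD CPG: making it excitatory (constant conductance, reversal 0 mV,
   or keeping the posterior-β modulation with the reversal flipped) or
   blocking it (conductance 0).  Not defined for the hind leg, which has
   no intersegmental synapse on its LD CPG.
2. **cpg_drive** — changing the central drives g_app of the leg's
   levator/depressor CPG neurons (strong excitation/inhibition or removal).
   The outcome is phase-dependent: the same permanent change may decouple
   the leg or leave its stepping unchanged, depending on where in the step
   cycle the command arrives.
3. **premotor_in** — changing the inhibitory inputs g_d to the two LD
   premotor interneurons.  A fully disinhibited premotor IN silences its
   motoneuron; an inhibited one frees its motoneuron to fire tonically.
   This acts downstream of the CPG and is effective at every phase.

Every mechanism is expressed as parameter edits applied at an onset time
and (optionally) reverted at an offset time, so decoupling is reversible
and coordination resumes when the command ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import gait
from .config import ModelConfig, LD_DRIVE_KEYS
from .core import E_EXC, E_INH
from .model import (IS_CONSTANT, IS_MODULATED, Command, ThreeLegModel,
                    Trajectory, build_model)

MECHANISMS = ("intersegmental_synapse", "cpg_drive", "premotor_in")

#: kernel override mode for "modulated with flipped reversal"
IS_MODULATED_OVERRIDE = 2


class DecouplingError(ValueError):
    """Invalid decoupling command (unknown mechanism/leg combination)."""


@dataclass
class DecouplingCommand:
    """One decoupling manipulation of one leg.

    ``onset`` is an absolute time in ms or a phase anchor
    ``("HL_liftoff", offset_ms)`` resolved against the baseline rhythm;
    ``offset_time`` (ms) optionally removes the override again.
    """
    mechanism: str
    leg: str
    variant: Union[str, Dict] = "default"
    onset: Union[float, Tuple[str, float]] = 0.0
    offset_time: Optional[float] = None

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise DecouplingError(f"unknown mechanism: {self.mechanism!r}")
        if self.leg not in ("FL", "ML", "HL"):
            raise DecouplingError(f"unknown leg: {self.leg!r}")
        if self.mechanism == "intersegmental_synapse" and self.leg == "HL":
            raise DecouplingError(
                "there are no intersegmental coordinating synapses on the "
                "LD CPG of the hind leg")


def _ld_keys(leg: str) -> Tuple[str, str]:
    return LD_DRIVE_KEYS[leg]


def apply_intersegmental_decoupling(model: ThreeLegModel, leg: str,
                                    variant: Union[str, Dict]) -> List[tuple]:
    """Override set for mechanism 1 (see Fig legend in :mod:`~stickwalk`).

    Variants: ``block`` (g = 0), ``make_excitatory`` (constant positive
    conductance, reversal 0 mV), ``make_excitatory_modulated`` (keep the
    posterior-β modulation, flip the reversal to 0 mV).  A dict variant
    may override ``g`` and ``E``.
    """
    if leg == "HL":
        raise DecouplingError(
            "there are no intersegmental coordinating synapses on the "
            "LD CPG of the hind leg")
    cfg = model.config
    g_exc = cfg.require("decoupling")["g_exc_const"]
    g_max = cfg.require("intersegmental")["g_inh3" if leg == "FL" else "g_inh9"]
    if isinstance(variant, dict):
        name = variant.get("variant", "make_excitatory")
        g_exc = variant.get("g", g_exc)
    else:
        name = variant
    if name == "block":
        return [("intersegmental", leg, IS_CONSTANT, 0.0, E_INH)]
    if name == "make_excitatory":
        return [("intersegmental", leg, IS_CONSTANT, g_exc, E_EXC)]
    if name == "make_excitatory_modulated":
        return [("intersegmental", leg, IS_MODULATED_OVERRIDE, g_max, E_EXC)]
    raise DecouplingError(f"unknown intersegmental variant: {name!r}")


def apply_cpg_drive_decoupling(model: ThreeLegModel, leg: str,
                               variant: Union[str, Dict]) -> List[tuple]:
    """Override set for mechanism 2: change the central drives to the
    leg's levator/depressor CPG neurons.

    Variants: ``lift`` (strong excitation of the levator, strong inhibition
    of the depressor), ``ground`` (the converse), ``zero`` (both drives
    removed).  "Strong" is ``strong_factor`` × the larger baseline LD
    drive of the current mode.  A dict variant maps drive keys (g_app3,
    ...) to (g, E_rev) pairs.
    """
    klev, kdep = _ld_keys(leg)
    if isinstance(variant, dict):
        edits = []
        for key, (g, E) in variant.items():
            if key not in (klev, kdep):
                raise DecouplingError(
                    f"drive key {key!r} does not belong to the {leg} LD CPG "
                    f"(expected {klev} or {kdep})")
            edits.append(("drive", key, g, E))
        return edits
    drives = model.config.mode_drives(model.mode)
    dec = model.config.require("decoupling")
    strong = dec["strong_factor"] * max(drives[klev], drives[kdep])
    if variant == "lift":
        if leg == "FL" and "fl_drive_command" in dec:
            cmd = dec["fl_drive_command"]
            return [("drive", klev, cmd["g_exc"], E_EXC),
                    ("drive", kdep, cmd["g_inh"], E_INH)]
        return [("drive", klev, strong, E_EXC), ("drive", kdep, strong, E_INH)]
    if variant == "ground":
        return [("drive", klev, strong, E_INH), ("drive", kdep, strong, E_EXC)]
    if variant == "zero":
        return [("drive", klev, 0.0, E_EXC), ("drive", kdep, 0.0, E_EXC)]
    raise DecouplingError(f"unknown cpg_drive variant: {variant!r}")


def apply_premotor_decoupling(model: ThreeLegModel, leg: str,
                              variant: Union[str, Dict]) -> List[tuple]:
    """Override set for mechanism 3: change the inhibitory inputs g_d to
    the LD premotor interneurons.

    ``lift``   — disinhibit the depressor premotor IN (silencing the
                 depressor MN) and inhibit the levator premotor IN
                 (enhancing the levator MN): the leg rises and stays up.
    ``ground`` — the converse: the leg stays on the ground.
    Effective regardless of the phase of the stepping period.
    """
    g_strong = model.config.require("decoupling")["g_d_strong"]
    key_lev = f"g_d_IN_{leg}_lev"
    key_dep = f"g_d_IN_{leg}_dep"
    if isinstance(variant, dict):
        return [("drive", k, g, E) for k, (g, E) in variant.items()]
    if variant == "lift":
        return [("drive", key_dep, 0.0, E_INH),       # fully disinhibited
                ("drive", key_lev, g_strong, E_INH)]  # inhibited
    if variant == "ground":
        return [("drive", key_lev, 0.0, E_INH),
                ("drive", key_dep, g_strong, E_INH)]
    raise DecouplingError(f"unknown premotor variant: {variant!r}")


_APPLY = {
    "intersegmental_synapse": apply_intersegmental_decoupling,
    "cpg_drive": apply_cpg_drive_decoupling,
    "premotor_in": apply_premotor_decoupling,
}


def revert_edits(model: ThreeLegModel, edits: Sequence[tuple]) -> List[tuple]:
    """Edits that restore the baseline values touched by ``edits``."""
    out = []
    for e in edits:
        if e[0] == "drive":
            g, E = model.baseline_drive(e[1])
            out.append(("drive", e[1], g, E))
        elif e[0] == "intersegmental":
            leg = e[1]
            inter = model.config.require("intersegmental")
            g_max = inter["g_inh3" if leg == "FL" else "g_inh9"]
            out.append(("intersegmental", leg, IS_MODULATED, g_max,
                        model.config.require("neuron", "E_inh")))
    return out


def build_commands(model: ThreeLegModel, dc: DecouplingCommand,
                   anchor_time: Optional[float] = None) -> List[Command]:
    """Translate a DecouplingCommand into scheduled parameter edits."""
    edits = _APPLY[dc.mechanism](model, dc.leg, dc.variant)
    if isinstance(dc.onset, tuple):
        kind, offset = dc.onset
        if kind != "HL_liftoff":
            raise DecouplingError(f"unknown onset anchor: {kind!r}")
        if anchor_time is None:
            raise DecouplingError(
                "anchored onset needs anchor_time (an HL lift-off time "
                "from a reference run)")
        t_on = anchor_time + offset
    else:
        t_on = float(dc.onset)
    label = f"{dc.mechanism}:{dc.leg}:{dc.variant}"
    cmds = [Command(t_on, edits, label=label)]
    if dc.offset_time is not None:
        cmds.append(Command(dc.offset_time, revert_edits(model, edits),
                            label=f"revert {label}"))
    return cmds


# ---------------------------------------------------------------------------

def classify_outcome(tr: Trajectory, leg: str, t_cmd: float,
                     tail_ms: float = 5000.0) -> str:
    """Label the target leg's state in the final ``tail_ms`` of a run:
    ``stepping`` if it still produces lift-offs, otherwise the posture of
    the stopped leg (e.g. ``lifted_protracted_extended``)."""
    t_end = tr.t[-1]
    ev = [e for e in tr.events(leg) if e.t > t_end - tail_ms]
    if any(e.kind == "liftoff" for e in ev):
        return "stepping"
    mask = tr.t >= t_end - min(tail_ms, 3000.0)
    ang = tr.angles(leg)[mask]
    try:
        posture = gait.classify_posture(ang[:, 0], ang[:, 1], ang[:, 2])
        return posture.label
    except gait.GaitError:
        return "other"


def reference_rhythm(cfg: ModelConfig, mode: str, t_ms: float = 16000.0,
                     skip_ms: float = 6000.0) -> Tuple[float, float]:
    """(anchor, period): a hind-leg lift-off time after the transient, and
    the mean stepping period, from an unperturbed run."""
    model = build_model(cfg, mode=mode)
    tr = model.run(t_ms)
    lo = np.array([e.t for e in tr.events("HL") if e.kind == "liftoff"])
    lo = lo[lo > skip_ms]
    if len(lo) < 3:
        raise DecouplingError("baseline run produced too few step cycles")
    return float(lo[0]), float(np.diff(lo).mean())


@dataclass
class SweepResult:
    """Outcome of an onset-phase sweep of one decoupling command."""
    mode: str
    period_ms: float
    anchor_ms: float               # HL lift-off the onset grid is locked to
    onsets_ms: List[float]
    outcomes: List[str]
    success_labels: Tuple[str, ...]

    @property
    def n_phases(self) -> int:
        return len(self.onsets_ms)

    @property
    def successes(self) -> List[bool]:
        return [o in self.success_labels for o in self.outcomes]

    @property
    def success_fraction(self) -> float:
        return float(np.mean(self.successes))

    def _longest_circular_run(self, values: List[bool]) -> int:
        n = len(values)
        if all(values):
            return n
        if not any(values):
            return 0
        doubled = values + values
        best = cur = 0
        for v in doubled:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        return min(best, n)

    @property
    def success_window_ms(self) -> float:
        """Length of the longest contiguous success window (circular),
        in ms of onset phase."""
        step = self.period_ms / self.n_phases
        return self._longest_circular_run(self.successes) * step

    @property
    def failure_window_ms(self) -> float:
        step = self.period_ms / self.n_phases
        return self._longest_circular_run([not s for s in self.successes]) * step

    @property
    def window_anchor_offset_ms(self) -> float:
        """Offset of the success-window start relative to the HL lift-off
        anchor, in ms (modulo one period)."""
        n = self.n_phases
        succ = self.successes
        if all(succ) or not any(succ):
            return 0.0
        # first success whose predecessor (circularly) is a failure
        for i in range(n):
            if succ[i] and not succ[(i - 1) % n]:
                return (self.onsets_ms[i] - self.anchor_ms) % self.period_ms
        return 0.0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "period_ms": self.period_ms,
            "anchor_ms": self.anchor_ms,
            "onsets_ms": self.onsets_ms,
            "outcomes": self.outcomes,
            "success_window_ms": self.success_window_ms,
            "failure_window_ms": self.failure_window_ms,
            "window_anchor_offset_ms": self.window_anchor_offset_ms,
            "success_fraction": self.success_fraction,
        }


def sweep_command_phase(cfg: ModelConfig, command_template: DecouplingCommand,
                        n_phases: int, mode: str,
                        t_total_ms: float = 20000.0,
                        tail_ms: float = 5000.0,
                        success_labels: Sequence[str] = (
                            "lifted_protracted_extended",),
                        record_dt: float = 2.0) -> SweepResult:
    """Apply one decoupling command at ``n_phases`` equally spaced onsets
    across one baseline stepping period (locked to a hind-leg lift-off)
    and label each outcome from the final ``tail_ms`` of a
    ``t_total_ms`` run.
    """
    if n_phases < 2:
        raise DecouplingError("need at least 2 onset phases")
    anchor, period = reference_rhythm(cfg, mode)
    onsets = [anchor + i * period / n_phases for i in range(n_phases)]
    outcomes = []
    for t_on in onsets:
        model = build_model(cfg, mode=mode)
        dc = DecouplingCommand(command_template.mechanism,
                               command_template.leg,
                               command_template.variant,
                               onset=t_on,
                               offset_time=command_template.offset_time)
        cmds = build_commands(model, dc)
        tr = model.run(t_total_ms, commands=cmds, record_dt=record_dt)
        outcomes.append(classify_outcome(tr, dc.leg, t_on, tail_ms))
    return SweepResult(mode=mode, period_ms=period, anchor_ms=anchor,
                       onsets_ms=onsets, outcomes=outcomes,
                       success_labels=tuple(success_labels))
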