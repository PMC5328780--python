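"""Step-event detection, coordination-pattern classification and posture labels.

The walking model reports each leg's coxa–trochanter elevation angle β(t).
Ground contact is defined by β: the leg is on the ground near β = 30° and
fully elevated at β = 60°.  A *lift-off* is an upward crossing of β through
the ground threshold, a *touch-down* a downward crossing.  Coordination
patterns are classified from lift-off phase lags between legs:

* tripod   — front and hind leg in phase, middle leg in anti-phase,
* tetrapod — lift-off order hind → middle → front with ≈1/3-period lags,
* stopped  — one or more legs produce no step events,
* unusual  — rhythmic but matching neither template.

This module is deliberately independent of the simulator so it can be
validated on synthetic square-wave traces (`make_fixture`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

LEGS = ("FL", "ML", "HL")

#: default ground-contact threshold for event detection (β is 30° on the
#: ground and 60° fully elevated; any value near the floor works)
GROUND_THRESHOLD = 33.0
HYSTERESIS = 1.0


class GaitError(ValueError):
    """Raised on malformed traces or insufficient data for classification."""


@dataclass(frozen=True)
class StepEvent:
    leg: str
    kind: str  # "liftoff" | "touchdown"
    t: float   # ms

    def to_dict(self) -> dict:
        return {"leg": self.leg, "kind": self.kind, "t_ms": self.t}


@dataclass
class Posture:
    """Steady posture of a stopped leg, labelled by the canonical positions.

    ``lifted_protracted_extended`` (α≈28, β≈60, γ≈45) and
    ``grounded_retracted_flexed`` (α≈128, β≈30, γ≈110) are the two fixed
    postures a decoupled pro-/mesothoracic leg settles into.  The hind leg
    rests grounded with the tibia *stretched* (γ≈45); that combination is
    reported as ``other:grounded_retracted_stretched``.
    """

    label: str
    alpha: float
    beta: float
    gamma: float

    def to_dict(self) -> dict:
        return {"label": self.label, "alpha": self.alpha,
                "beta": self.beta, "gamma": self.gamma}


@dataclass
class GaitSummary:
    pattern: str                                  # tripod|tetrapod|unusual|stopped
    stopped_legs: Tuple[str, ...] = ()
    period_mean: Dict[str, float] = field(default_factory=dict)   # ms per leg
    period_cv: Dict[str, float] = field(default_factory=dict)
    phase: Dict[str, float] = field(default_factory=dict)         # "FL-HL" etc.
    n_cycles: Dict[str, int] = field(default_factory=dict)
    postures: Dict[str, Posture] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "pattern": self.pattern,
            "stopped_legs": list(self.stopped_legs),
            "period_mean_ms": self.period_mean,
            "period_cv": self.period_cv,
            "phase": self.phase,
            "n_cycles": self.n_cycles,
        }
        if self.postures:
            d["postures"] = {k: v.to_dict() for k, v in self.postures.items()}
        return d

    def to_json(self, path=None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def detect_events(t: np.ndarray, beta: np.ndarray, *,
                  ground_threshold: float = GROUND_THRESHOLD,
                  hysteresis: float = HYSTERESIS,
                  leg: str = "") -> List[StepEvent]:
    """Detect debounced lift-off / touch-down events from a β(t) trace.

    A Schmitt trigger around ``ground_threshold`` (± ``hysteresis``)
    suppresses chatter from ripple smaller than the hysteresis band.  Event
    times are linearly interpolated at the threshold crossing.  The trace
    must be uniformly sampled.
    """
    t = np.asarray(t, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if t.ndim != 1 or t.shape != beta.shape or t.size < 2:
        raise GaitError("need matching 1-d t and beta arrays with >= 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise GaitError("non-uniform sampling interval in beta trace")

    lo = ground_threshold - hysteresis
    hi = ground_threshold + hysteresis
    # initial state: grounded / lifted by position relative to the threshold
    state = 1 if beta[0] > ground_threshold else 0  # 1 = lifted
    events: List[StepEvent] = []
    for i in range(1, t.size):
        b = beta[i]
        if state == 0 and b > hi:
            tc = _interp_crossing(t[i - 1], t[i], beta[i - 1], b, ground_threshold)
            events.append(StepEvent(leg, "liftoff", tc))
            state = 1
        elif state == 1 and b < lo:
            tc = _interp_crossing(t[i - 1], t[i], beta[i - 1], b, ground_threshold)
            events.append(StepEvent(leg, "touchdown", tc))
            state = 0
    return events


def _interp_crossing(t0, t1, b0, b1, thr):
    if b1 == b0:
        return t1
    frac = (thr - b0) / (b1 - b0)
    frac = min(max(frac, 0.0), 1.0)
    return t0 + frac * (t1 - t0)


def liftoff_times(events: Iterable[StepEvent]) -> np.ndarray:
    return np.array([e.t for e in events if e.kind == "liftoff"])


def stance_intervals(events: Sequence[StepEvent], t_end: float,
                     t_start: float = 0.0) -> List[Tuple[float, float]]:
    """Per-leg stance (ground-contact) intervals, for podogram bar plots."""
    out = []
    down: Optional[float] = None
    first = True
    for e in sorted(events, key=lambda e: e.t):
        if e.kind == "touchdown":
            down = e.t
            first = False
        else:  # liftoff
            out.append((t_start if first else (down if down is not None else t_start), e.t))
            down = None
            first = False
    if down is not None or first:
        out.append((down if down is not None else t_start, t_end))
    return out


def podogram_frame(events_by_leg: Mapping[str, Sequence[StepEvent]],
                   t_end: float, t_start: float = 0.0) -> pd.DataFrame:
    rows = []
    for leg, ev in events_by_leg.items():
        for on, off in stance_intervals(ev, t_end, t_start):
            rows.append({"leg": leg, "t_on": on, "t_off": off})
    return pd.DataFrame(rows, columns=["leg", "t_on", "t_off"])


def _circmean(x: np.ndarray) -> float:
    ang = 2 * np.pi * x
    return float(np.mod(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
                        / (2 * np.pi), 1.0))


def _circdist(a: float, b: float) -> float:
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


def pairwise_phase(lift_a: np.ndarray, lift_b: np.ndarray) -> float:
    """Mean phase of leg A's lift-offs within leg B's step cycle, in [0, 1)."""
    if len(lift_a) < 2 or len(lift_b) < 2:
        raise GaitError("need >= 2 lift-offs per leg for a phase estimate")
    phases = []
    for ta in lift_a:
        k = np.searchsorted(lift_b, ta, side="right") - 1
        if k < 0 or k + 1 >= len(lift_b):
            continue
        period = lift_b[k + 1] - lift_b[k]
        phases.append((ta - lift_b[k]) / period)
    if not phases:
        raise GaitError("no overlapping cycles between legs")
    return _circmean(np.array(phases))


def classify_pattern(events_by_leg: Mapping[str, Sequence[StepEvent]],
                     t_end: Optional[float] = None, *,
                     min_cycles: int = 5,
                     tol: float = 0.1,
                     stopped_after: float = 2.0) -> GaitSummary:
    """Classify the coordination pattern from per-leg step events.

    tripod   iff |phase(FL,HL)| < tol and |phase(ML,HL) - 1/2| < tol
    tetrapod iff phase(ML,HL) and phase(FL,ML) both within 1/3 ± tol
               (lift-off order HL → ML → FL)
    stopped  if a leg has no events during the last ``stopped_after``
               reference periods of the record
    unusual  otherwise.

    Stopped legs are excluded from phase computation.  Raises
    :class:`GaitError` when fewer than ``min_cycles`` complete cycles are
    available on every non-stopped leg.
    """
    lifts = {leg: liftoff_times(events_by_leg.get(leg, ()))
             for leg in LEGS}
    if t_end is None:
        allt = [e.t for ev in events_by_leg.values() for e in ev]
        t_end = max(allt) if allt else 0.0

    # reference period from the leg with the most cycles
    ref_periods = [np.diff(lt).mean() for lt in lifts.values() if len(lt) >= 2]
    ref = float(np.median(ref_periods)) if ref_periods else np.inf

    stopped = []
    for leg in LEGS:
        lt = lifts[leg]
        if len(lt) < 2 or (np.isfinite(ref)
                           and t_end - lt[-1] > stopped_after * ref):
            stopped.append(leg)
    active = [leg for leg in LEGS if leg not in stopped]

    summary = GaitSummary(pattern="unusual", stopped_legs=tuple(stopped))
    for leg in active:
        per = np.diff(lifts[leg])
        if len(per) < min_cycles:
            raise GaitError(
                f"insufficient data: leg {leg} has {len(per)} cycles, "
                f"need {min_cycles}")
        summary.period_mean[leg] = float(per.mean())
        summary.period_cv[leg] = float(per.std() / per.mean())
        summary.n_cycles[leg] = int(len(per))

    for (a, b) in (("FL", "HL"), ("ML", "HL"), ("FL", "ML")):
        if a in active and b in active:
            summary.phase[f"{a}-{b}"] = pairwise_phase(lifts[a], lifts[b])

    if stopped:
        summary.pattern = "stopped"
        return summary

    p_fl_hl = summary.phase["FL-HL"]
    p_ml_hl = summary.phase["ML-HL"]
    p_fl_ml = summary.phase["FL-ML"]
    if _circdist(p_fl_hl, 0.0) < tol and _circdist(p_ml_hl, 0.5) < tol:
        summary.pattern = "tripod"
    elif (_circdist(p_ml_hl, 1 / 3) < tol and _circdist(p_fl_ml, 1 / 3) < tol):
        summary.pattern = "tetrapod"
    else:
        summary.pattern = "unusual"
    return summary


def classify_posture(alpha: np.ndarray, beta: np.ndarray, gamma: np.ndarray,
                     *, steady_range: float = 1.0,
                     tol: float = 6.0) -> Posture:
    """Label the steady posture of a stopped leg from a trailing angle slice.

    The slice must be steady (peak-to-peak range < ``steady_range`` degrees
    on every angle), otherwise a :class:`GaitError` is raised and the caller
    should extend the simulation.
    """
    for name, x in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        x = np.asarray(x, float)
        if x.size == 0:
            raise GaitError("empty angle slice")
        if np.ptp(x) >= steady_range:
            raise GaitError(f"non-steady slice: {name} range {np.ptp(x):.2f} deg")
    a, b, g = (float(np.mean(alpha)), float(np.mean(beta)),
               float(np.mean(gamma)))

    def near(x, target):
        return abs(x - target) < tol

    if near(b, 60) and near(a, 28) and near(g, 45):
        label = "lifted_protracted_extended"
    elif near(b, 30) and near(a, 128) and near(g, 110):
        label = "grounded_retracted_flexed"
    elif near(b, 30) and near(a, 128) and near(g, 45):
        label = "other:grounded_retracted_stretched"
    elif near(b, 60) and near(a, 28) and near(g, 110):
        label = "other:lifted_protracted_flexed"
    else:
        label = "other"
    return Posture(label, a, b, g)


def make_fixture(period_ms: float, duty: float, lags: Sequence[float],
                 n_cycles: int, noise: float = 0.0,
                 seed: Optional[int] = None, dt: float = 1.0,
                 beta_low: float = 30.0, beta_high: float = 60.0
                 ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Synthetic square-wave β traces for the three legs.

    ``duty`` is the *lifted* (swing) fraction of the cycle; ``lags`` are the
    lift-off phases of (FL, ML, HL) as fractions of the period.  With
    ``noise > 0`` seeded Gaussian noise is added, so identical seeds give
    identical traces.
    """
    if not 0.0 < duty < 1.0:
        raise GaitError("duty must lie strictly between 0 and 1")
    if len(lags) != 3:
        raise GaitError("need one lag per leg (FL, ML, HL)")
    t = np.arange(0.0, n_cycles * period_ms + dt / 2, dt)
    rng = np.random.default_rng(seed)
    traces: Dict[str, np.ndarray] = {}
    for leg, lag in zip(LEGS, lags):
        phase = np.mod(t / period_ms - lag, 1.0)
        beta = np.where(phase < duty, beta_high, beta_low).astype(float)
        if noise > 0:
            beta = beta + rng.normal(0.0, noise, size=beta.shape)
        traces[leg] = beta
    return t, traces


def summarize_traces(t: np.ndarray, beta_by_leg: Mapping[str, np.ndarray],
                     angles_by_leg: Optional[Mapping[str, np.ndarray]] = None,
                     *, ground_threshold: float = GROUND_THRESHOLD,
                     hysteresis: float = HYSTERESIS,
                     posture_tail_ms: float = 2000.0,
                     **classify_kw) -> GaitSummary:
    """End-to-end reading of a simulation: events → pattern → postures.

    ``angles_by_leg`` optionally maps a leg to an (n, 3) array of
    (α, β, γ) used to label the posture of stopped legs from the final
    ``posture_tail_ms`` of the record.
    """
    events = {leg: detect_events(t, beta, leg=leg,
                                 ground_threshold=ground_threshold,
                                 hysteresis=hysteresis)
              for leg, beta in beta_by_leg.items()}
    summary = classify_pattern(events, t_end=float(t[-1]), **classify_kw)
    if angles_by_leg is not None:
        mask = t >= t[-1] - posture_tail_ms
        for leg in summary.stopped_legs:
            if leg in angles_by_leg:
                ang = np.asarray(angles_by_leg[leg])[mask]
                try:
                    summary.postures[leg] = classify_posture(
                        ang[:, 0], ang[:, 1], ang[:, 2])
                except GaitError:
                    summary.postures[leg] = Posture(
                        "other", *np.mean(ang, axis=0))
    return summary
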