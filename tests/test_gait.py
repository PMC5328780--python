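"""Gait analysis on synthetic traces: events, classification, postures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stickwalk import gait
from stickwalk.gait import (GaitError, classify_pattern, classify_posture,
                            detect_events, make_fixture, summarize_traces)


# ---------------------------------------------------------------------------
# event detection

def test_square_wave_event_counts_and_times():
    t, traces = make_fixture(600.0, 0.5, [0.0, 0.5, 0.0], 10, dt=1.0)
    ev = detect_events(t, traces["HL"], leg="HL")
    lifts = [e for e in ev if e.kind == "liftoff"]
    downs = [e for e in ev if e.kind == "touchdown"]
    assert len(lifts) == 10 and len(downs) == 10
    # lift-offs at multiples of the period, within one sample (the trace
    # starts lifted, so the first detected lift-off is at one full period)
    for k, e in enumerate(lifts):
        assert abs(e.t - (k + 1) * 600.0) <= 1.0 + 1e-9
    for k, e in enumerate(downs):
        assert abs(e.t - (k * 600.0 + 300.0)) <= 1.0 + 1e-9


def test_constant_trace_has_no_events_and_is_stopped():
    t = np.arange(0.0, 6000.0)
    ev = detect_events(t, np.full_like(t, 60.0), leg="FL")
    assert ev == []
    t2, traces = make_fixture(600.0, 0.5, [0, 0.5, 0], 10)
    events = {"FL": [], "ML": detect_events(t2, traces["ML"], leg="ML"),
              "HL": detect_events(t2, traces["HL"], leg="HL")}
    summary = classify_pattern(events, t_end=float(t2[-1]))
    assert summary.pattern == "stopped"
    assert summary.stopped_legs == ("FL",)


def test_subthreshold_ripple_is_debounced():
    t, traces = make_fixture(600.0, 0.5, [0, 0.5, 0], 10, dt=1.0)
    clean = detect_events(t, traces["HL"], leg="HL")
    rng = np.random.default_rng(7)
    # ripple strictly inside the hysteresis band around the threshold
    noisy = traces["HL"] + 0.8 * np.sin(2 * np.pi * t / 37.0)
    ev = detect_events(t, noisy, leg="HL")
    assert len(ev) == len(clean)


def test_nonuniform_sampling_rejected():
    t = np.array([0.0, 1.0, 3.0, 4.0])
    with pytest.raises(GaitError, match="non-uniform"):
        detect_events(t, np.array([30.0, 60.0, 30.0, 60.0]))


# ---------------------------------------------------------------------------
# pattern classification

@pytest.mark.parametrize("period,duty,lags,expected", [
    (600.0, 0.5, [0.0, 0.5, 0.0], "tripod"),
    (1180.0, 1 / 3, [2 / 3, 1 / 3, 0.0], "tetrapod"),
    (800.0, 0.4, [0.08, 0.55, 0.0], "tripod"),      # within 0.1 tolerance
    (800.0, 0.4, [0.25, 0.75, 0.0], "unusual"),
])
def test_classify_pattern_templates(period, duty, lags, expected):
    t, traces = make_fixture(period, duty, lags, 12)
    assert summarize_traces(t, traces).pattern == expected


def test_insufficient_cycles_raise():
    t, traces = make_fixture(600.0, 0.5, [0, 0.5, 0], 3)
    with pytest.raises(GaitError, match="insufficient"):
        summarize_traces(t, traces)


def test_classifier_roundtrip_on_jittered_fixtures():
    """100 fixtures drawn near the tripod/tetrapod templates (lag jitter
    < 0.05 period) are all recovered."""
    rng = np.random.default_rng(42)
    hits = 0
    for i in range(100):
        if i % 2 == 0:
            base, expected = [0.0, 0.5, 0.0], "tripod"
            period, duty = 615.0, 0.5
        else:
            base, expected = [2 / 3, 1 / 3, 0.0], "tetrapod"
            period, duty = 1180.0, 1 / 3
        lags = [b + rng.uniform(-0.045, 0.045) for b in base]
        t, traces = make_fixture(period, duty, lags, 10)
        if summarize_traces(t, traces).pattern == expected:
            hits += 1
    assert hits == 100


@settings(derandomize=True, max_examples=25, deadline=None)
@given(period=st.floats(400.0, 1500.0), duty=st.floats(0.2, 0.8),
       lag_ml=st.floats(0.05, 0.95))
def test_period_estimator_and_phase_additivity(period, duty, lag_ml):
    """On noise-free fixtures the estimated period matches the requested one
    within a sample, and pairwise phases are additive modulo 1."""
    t, traces = make_fixture(period, duty, [0.27, lag_ml, 0.0], 10, dt=1.0)
    s = summarize_traces(t, traces)
    for leg in ("FL", "ML", "HL"):
        assert abs(s.period_mean[leg] - period) <= 2.0
    resid = (s.phase["FL-ML"] + s.phase["ML-HL"] - s.phase["FL-HL"]) % 1.0
    assert min(resid, 1.0 - resid) < 0.02


def test_fixture_determinism_and_validation():
    t1, a = make_fixture(600.0, 0.5, [0, 0.5, 0], 5, noise=1.0, seed=3)
    t2, b = make_fixture(600.0, 0.5, [0, 0.5, 0], 5, noise=1.0, seed=3)
    assert all(np.array_equal(a[leg], b[leg]) for leg in a)
    with pytest.raises(GaitError):
        make_fixture(600.0, 1.2, [0, 0.5, 0], 5)


# ---------------------------------------------------------------------------
# posture labels

@pytest.mark.parametrize("angles,label", [
    ((28.0, 60.0, 45.0), "lifted_protracted_extended"),
    ((128.0, 30.0, 110.0), "grounded_retracted_flexed"),
    ((128.0, 30.0, 45.0), "other:grounded_retracted_stretched"),
    ((28.0, 60.0, 110.0), "other:lifted_protracted_flexed"),
    ((80.0, 45.0, 80.0), "other"),
])
def test_posture_labels(angles, label):
    n = 500
    a, b, g = (np.full(n, angles[0]), np.full(n, angles[1]),
               np.full(n, angles[2]))
    assert classify_posture(a, b, g).label == label


def test_posture_requires_steady_slice():
    n = 500
    with pytest.raises(GaitError, match="non-steady"):
        classify_posture(np.linspace(28, 40, n), np.full(n, 60.0),
                         np.full(n, 45.0))


def test_podogram_stance_intervals():
    t, traces = make_fixture(600.0, 0.5, [0, 0.5, 0], 4, dt=1.0)
    ev = {leg: detect_events(t, b, leg=leg) for leg, b in traces.items()}
    df = gait.podogram_frame(ev, t_end=float(t[-1]))
    hl = df[df.leg == "HL"]
    # stance = grounded half of each cycle
    assert np.allclose(hl.t_off - hl.t_on, 300.0, atol=2.0)
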