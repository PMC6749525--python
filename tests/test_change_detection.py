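"""SMA computation and the classifier gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actigate.change_detection import (
    CARRY_OVER,
    CLASSIFY_CHANGE,
    CLASSIFY_FORCED,
    SMASeries,
    compute_sma,
    decide,
    gate,
    gate_trace_frame,
    sma_series,
)


def test_sma_of_all_zero_window_is_zero():
    assert compute_sma(np.zeros((90, 3))) == 0.0


def test_sma_hand_computed_two_samples():
    window = np.array([[1.0, 2.0, 0.0], [-1.0, 2.0, 0.0]])
    assert compute_sma(window, use_half=False) == pytest.approx(3.0)


def test_sma_half_window_matches_brute_force():
    rng = np.random.default_rng(31)
    window = rng.normal(size=(90, 3))
    expected = sum(abs(x) + abs(y) + abs(z) for x, y, z in window[45:]) / 45
    assert compute_sma(window, use_half=True) == pytest.approx(expected, rel=1e-12)


def test_sma_half_window_uses_newest_ceil_half():
    window = np.vstack([np.zeros((45, 3)), np.ones((45, 3))])
    assert compute_sma(window, use_half=True) == pytest.approx(3.0)
    odd = np.vstack([np.zeros((4, 3)), np.ones((5, 3))])  # ceil(9/2) = 5 newest
    assert compute_sma(odd, use_half=True) == pytest.approx(3.0)


def test_sma_empty_window_is_an_error():
    with pytest.raises(ValueError):
        compute_sma(np.empty((0, 3)))


@pytest.mark.parametrize(
    "sma_t,sma_prev,expected",
    [
        (0.5, 0.1, True),
        (0.50, 0.45, False),
        (0.3, 0.1, True),  # difference exactly at the threshold fires
        (0.1, 0.5, True),  # decreases fire too (absolute difference)
    ],
)
def test_decide_threshold_rule(sma_t, sma_prev, expected):
    assert decide(sma_t, sma_prev, threshold=0.2) is expected


def test_decide_rejects_negative_threshold():
    with pytest.raises(ValueError):
        decide(1.0, 1.0, threshold=-0.1)


@given(
    a=st.floats(0, 50, allow_nan=False),
    b=st.floats(0, 50, allow_nan=False),
    t=st.floats(0, 5, allow_nan=False),
)
@settings(deadline=None, derandomize=True)
def test_decide_is_symmetric(a, b, t):
    assert decide(a, b, t) == decide(b, a, t)


def test_gate_constant_sma_forces_every_n_windows():
    series = SMASeries(values=np.full(91, 9.81))
    decisions = gate(series, threshold=0.2, force_interval=30)
    calls = [d.window_index for d in decisions if d.invokes_classifier]
    assert calls == [0, 30, 60, 90]
    assert decisions[0].verdict == CLASSIFY_CHANGE
    assert all(decisions[i].verdict == CLASSIFY_FORCED for i in (30, 60, 90))
    assert sum(d.verdict == CARRY_OVER for d in decisions) == 87


def test_zero_threshold_classifies_every_window():
    series = SMASeries(values=np.abs(np.sin(np.arange(50))))
    decisions = gate(series, threshold=0.0, force_interval=30)
    assert all(d.verdict == CLASSIFY_CHANGE for d in decisions)


def test_alternating_sma_classifies_every_window():
    series = SMASeries(values=np.tile([0.0, 1.0], 25))
    decisions = gate(series, threshold=0.2, force_interval=30)
    assert all(d.verdict == CLASSIFY_CHANGE for d in decisions)


def test_constant_sma_call_count_closed_form():
    """calls = 1 + floor((M-1)/N) on constant-SMA streams."""
    for M in range(1, 301):
        series = SMASeries(values=np.ones(M))
        n_calls = sum(d.invokes_classifier for d in gate(series, 0.2, 30))
        assert n_calls == 1 + (M - 1) // 30, M


@given(st.lists(st.floats(0, 30, allow_nan=False), min_size=2, max_size=120))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_total_calls_non_increasing_in_threshold(values):
    series = SMASeries(values=np.array(values))
    counts = [
        sum(d.invokes_classifier for d in gate(series, t, 30))
        for t in (0.0, 0.1, 0.2, 0.5, 1.0, 5.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_gate_first_window_always_classifies():
    series = SMASeries(values=np.array([3.0]))
    (only,) = gate(series, threshold=0.2, force_interval=30)
    assert only.verdict == CLASSIFY_CHANGE
    assert only.sma_delta is None


def test_gate_empty_series_yields_empty_output():
    assert gate(SMASeries(values=np.empty(0)), 0.2, 30) == []


def test_gate_validation():
    series = SMASeries(values=np.ones(5))
    with pytest.raises(ValueError):
        gate(series, threshold=0.2, force_interval=0)
    with pytest.raises(ValueError):
        gate(series, threshold=-1.0, force_interval=30)
    with pytest.raises(ValueError):
        SMASeries(values=np.array([-1.0]))


def test_gate_trace_frame_layout():
    series = SMASeries(values=np.array([1.0, 1.0, 5.0]))
    decisions = gate(series, threshold=0.2, force_interval=30)
    frame = gate_trace_frame(series, decisions)
    assert list(frame.columns) == ["window_index", "sma", "sma_delta", "verdict"]
    assert list(frame["verdict"]) == [CLASSIFY_CHANGE, CARRY_OVER, CLASSIFY_CHANGE]
    assert frame["sma_delta"].iloc[2] == pytest.approx(4.0)


def test_sma_series_over_windows(profiles):
    import actigate as ag

    sched = ag.ActivitySchedule(entries=(("sitting", 30.0),), seed=12)
    run = ag.generate_stream(sched, profiles).runs[0]
    windows = ag.segment_run(run)
    series = sma_series(windows, use_half=True)
    assert len(series) == len(windows)
    assert series.half_window
    assert np.all(series.values >= 0)
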