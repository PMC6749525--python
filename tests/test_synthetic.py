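"""Synthetic stream generator: determinism, labelling, SMA structure."""

import numpy as np
import pytest

import actigate as ag
from actigate.change_detection import compute_sma
from actigate.synthetic import G, ActivityProfile, ActivitySchedule, default_profiles, mix_vector


def test_noiseless_static_stream_is_pure_gravity():
    prof = {"sitting": ActivityProfile("sitting", (0.0, 0.0, 1.0), noise_sd=0.0)}
    sched = ActivitySchedule(entries=(("sitting", 10.0),), seed=0)
    stream = ag.generate_stream(sched, prof)
    run = stream.runs[0]
    assert len(run) == 200
    np.testing.assert_array_equal(run.xyz, np.tile([0.0, 0.0, G], (200, 1)))


def test_same_seed_gives_bitwise_identical_streams(profiles):
    sched = ActivitySchedule(entries=(("walking", 30.0), ("sitting", 30.0)), seed=42)
    a = ag.generate_stream(sched, profiles).runs[0]
    b = ag.generate_stream(sched, profiles).runs[0]
    np.testing.assert_array_equal(a.xyz, b.xyz)
    np.testing.assert_array_equal(a.timestamps, b.timestamps)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_jogging_section_has_higher_window_sma(profiles):
    sched = ActivitySchedule(entries=(("walking", 60.0), ("jogging", 60.0)), seed=5)
    run = ag.generate_stream(sched, profiles).runs[0]
    windows = ag.segment_run(run)
    sma = np.array([compute_sma(w, use_half=False) for w in windows])
    labels = np.array([w.true_label for w in windows])
    assert sma[labels == "jogging"].mean() > sma[labels == "walking"].mean()


def test_default_profiles_cover_exactly_six_activities(profiles):
    assert len(profiles) == 6
    assert set(profiles) == {"walking", "jogging", "upstairs", "downstairs", "sitting", "standing"}
    for label in ("sitting", "standing"):
        assert profiles[label].body_amplitude == 0.0


def test_noiseless_sitting_window_sma_closed_form():
    # constant signal g*o => SMA = g * (|o_x| + |o_y| + |o_z|)
    o = np.array([0.6, 0.0, 0.8])
    prof = {"sitting": ActivityProfile("sitting", tuple(o), noise_sd=0.0)}
    sched = ActivitySchedule(entries=(("sitting", 3.0),), seed=0)
    run = ag.generate_stream(sched, prof).runs[0]
    sma = compute_sma(run.xyz[:45], use_half=False)
    assert sma == pytest.approx(G * np.abs(o).sum(), rel=1e-12)


def test_jogging_minus_walking_sma_exceeds_gate_threshold(profiles):
    gap = []
    for seed in (1, 2, 3):
        entries = ActivitySchedule(entries=(("walking", 60.0),), seed=seed)
        w_run = ag.generate_stream(entries, profiles).runs[0]
        entries = ActivitySchedule(entries=(("jogging", 60.0),), seed=seed)
        j_run = ag.generate_stream(entries, profiles).runs[0]
        w_sma = np.mean([compute_sma(w) for w in ag.segment_run(w_run)])
        j_sma = np.mean([compute_sma(w) for w in ag.segment_run(j_run)])
        gap.append(j_sma - w_sma)
    assert min(gap) > 0.2


def test_label_counts_follow_schedule_durations(profiles):
    sched = ActivitySchedule(
        entries=(("walking", 10.0), ("sitting", 7.3), ("jogging", 12.2)), seed=9
    )
    run = ag.generate_stream(sched, profiles, fs=20.0).runs[0]
    counts = dict(zip(*np.unique(run.labels, return_counts=True)))
    for label, dur in sched.entries:
        assert abs(counts[label] - dur * 20.0) <= 1


def test_sma_separability_dynamic_vs_static(profiles):
    """Between-activity SMA gap exceeds 3x the within-activity spread."""
    per_label = {}
    for label in profiles:
        sched = ActivitySchedule(entries=((label, 90.0),), seed=11)
        run = ag.generate_stream(sched, profiles).runs[0]
        values = np.array([compute_sma(w) for w in ag.segment_run(run)])
        per_label[label] = (values.mean(), values.std())
    for dyn in ("walking", "jogging", "upstairs", "downstairs"):
        for stat in ("sitting", "standing"):
            gap = abs(per_label[dyn][0] - per_label[stat][0])
            within = max(per_label[dyn][1], per_label[stat][1])
            assert gap > 3 * within, (dyn, stat, gap, within)


def test_missing_profile_error_names_the_label(profiles):
    sched = ActivitySchedule(entries=(("cartwheeling", 5.0),), seed=0)
    with pytest.raises(KeyError, match="cartwheeling"):
        ag.generate_stream(sched, profiles)


def test_generator_input_validation(profiles):
    with pytest.raises(ValueError):
        ag.generate_stream(
            ActivitySchedule(entries=(("walking", 5.0),), seed=0), profiles, fs=0.0
        )
    with pytest.raises(ValueError):
        ActivitySchedule(entries=(("walking", -1.0),), seed=0)
    with pytest.raises(ValueError):
        ActivityProfile("walking", (1.0, 1.0, 0.0))  # not a unit vector
    with pytest.raises(ValueError):
        ActivityProfile("sitting", (0.0, 0.0, 1.0), body_amplitude=1.0)  # static must be still


@pytest.mark.parametrize(
    "orientation",
    [(0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (0.6, 0.0, 0.8), (0.577350269, 0.577350269, 0.577350269)],
)
def test_mix_vector_is_unit_and_orthogonal(orientation):
    o = np.asarray(orientation)
    m = mix_vector(o)
    assert np.linalg.norm(m) == pytest.approx(1.0, abs=1e-12)
    assert float(m @ o) == pytest.approx(0.0, abs=1e-9)
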