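"""Event detection: velocity computation, zero crossings, bilateral checks."""

import numpy as np
import pytest

from treadgait.gait_events import (
    EventDetectionConfig,
    GaitEvent,
    ap_velocity,
    detect_events,
    detect_side_events,
    validate_event_sequence,
)
from treadgait.joints import JOINT_INDEX

from conftest import make_static_seq

AL = "ankle_left"


def _seq_with_ap(values, fs=15.0):
    seq = make_static_seq(n=len(values), fs=fs)
    seq.positions[:, JOINT_INDEX[AL], 1] = values
    return seq


def test_linear_ramp_gives_constant_velocity():
    t = np.arange(30) / 15.0
    _, vel, valid = ap_velocity(_seq_with_ap(-1200.0 * t), AL)
    assert valid.sum() >= 26  # only full-window edge frames are dropped
    np.testing.assert_allclose(vel[valid], -1200.0, rtol=1e-9)


def test_constant_position_gives_zero_velocity():
    _, vel, valid = ap_velocity(_seq_with_ap(np.full(30, 800.0)), AL)
    np.testing.assert_allclose(vel[valid], 0.0, atol=1e-9)


def test_sampled_sine_velocity_matches_brute_force_and_analytic_bound():
    fs, f = 15.0, 0.8
    t = np.arange(90) / fs
    y = 40.0 * np.sin(2 * np.pi * f * t)
    times, vel, valid = ap_velocity(_seq_with_ap(y), AL)
    # independent brute force: same 3-frame average then central difference
    y_s = np.convolve(y, np.ones(3) / 3, mode="same")
    brute = np.full_like(y, np.nan)
    brute[1:-1] = (y_s[2:] - y_s[:-2]) * fs / 2.0
    inner = np.zeros_like(valid)
    inner[2:-2] = True  # edges use shrunk windows; compare interior only
    np.testing.assert_allclose(vel[inner], brute[inner], rtol=1e-9)
    analytic = 40.0 * 2 * np.pi * f * np.cos(2 * np.pi * f * t)
    bound = np.abs(brute[inner] - analytic[inner]).max()  # O(dt^2) + smoothing term
    assert np.abs(vel[inner] - analytic[inner]).max() <= bound + 1e-9


def test_too_few_valid_frames_yields_empty_series():
    seq = make_static_seq(n=10)
    seq.valid[2:, JOINT_INDEX[AL]] = False
    t, vel, valid = ap_velocity(seq, AL)
    assert t.size == vel.size == valid.size == 0


def test_invalid_samples_propagate_into_velocity():
    seq = _seq_with_ap(np.linspace(0, 290, 30))
    seq.valid[10, JOINT_INDEX[AL]] = False
    _, _, valid = ap_velocity(seq, AL)
    # smoothing window 3 + central difference touch frames 8..12
    assert not valid[8:13].any()
    assert valid[2:8].all() and valid[13:-2].all()


def test_triangle_wave_events_at_extrema():
    """Sawtooth AP position: heel-down at each maximum, toe-up at each
    minimum, to within one frame; counts equal a brute-force sign-change
    scan of the finite differences."""
    fs, period, n = 15.0, 1.3, 300
    t = np.arange(n) / fs
    phase = np.mod(t, period) / period
    y = 200.0 * np.where(phase < 0.5, 1 - 4 * phase, -3 + 4 * phase)  # max at phase 0
    seq = _seq_with_ap(y)
    events = detect_side_events(seq, "left")
    hd = np.array([e.time for e in events if e.kind == "heel_down"])
    tu = np.array([e.time for e in events if e.kind == "toe_up"])
    true_hd = np.arange(period, t[-1] - 0.1, period)  # skip the t=0 boundary maximum
    true_tu = np.arange(period / 2, t[-1] - 0.1, period)
    assert len(hd) == len(true_hd) and len(tu) == len(true_tu)
    assert np.abs(hd - true_hd).max() <= 1 / fs
    assert np.abs(tu - true_tu).max() <= 1 / fs
    # brute-force oracle: sign changes of raw first differences
    dv = np.sign(np.diff(y))
    flips = np.flatnonzero(dv[:-1] != dv[1:])
    assert len(events) == len(flips)


def test_constant_sign_velocity_yields_no_events():
    t = np.arange(40) / 15.0
    events = detect_events(t, np.full(40, -500.0), np.ones(40, bool), "left")
    assert events == []


def test_noiseless_walk_recovers_every_event_within_one_frame(clean_walk):
    seq, truth = clean_walk
    fs = truth.config.fs
    for side in ("left", "right"):
        events = detect_side_events(seq, side)
        for kind in ("heel_down", "toe_up"):
            det = np.array([e.time for e in events if e.kind == kind])
            true = truth.true_events(side, kind)
            true = true[(true > 0.2) & (true < seq.timestamps[-1] - 0.2)]
            err = np.abs(det[np.argmin(np.abs(det[:, None] - true[None, :]), axis=0)] - true)
            assert err.max() <= 1.0 / fs


def test_event_sequence_alternates_strictly(clean_walk):
    seq, _ = clean_walk
    for side in ("left", "right"):
        events = detect_side_events(seq, side)
        kinds = [e.kind for e in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        times = [e.time for e in events]
        assert all(b > a for a, b in zip(times, times[1:]))


def test_time_shift_equivariance(clean_walk):
    seq, _ = clean_walk
    shifted = seq.copy()
    delta = 37.5
    shifted.timestamps = seq.timestamps + delta
    e0 = detect_side_events(seq, "left")
    e1 = detect_side_events(shifted, "left")
    assert len(e0) == len(e1)
    np.testing.assert_allclose(
        [e.time for e in e1], [e.time + delta for e in e0], atol=1e-6
    )


def test_belt_speed_offset_invariance():
    """Adding a velocity offset that flips no stance/swing sign leaves the
    event count unchanged."""
    t = np.arange(200) / 15.0
    vel = 600.0 * np.sign(np.sin(2 * np.pi * t / 1.2)) + 0.0
    valid = np.ones(t.size, bool)
    n0 = len(detect_events(t, vel, valid, "left"))
    n1 = len(detect_events(t, vel + 150.0, valid, "left"))
    assert n0 == n1 > 0


def test_debounce_rejects_jitter_double_crossings():
    t = np.arange(60) / 15.0
    vel = np.full(60, 400.0)
    vel[20] = -50.0  # genuine-looking crossing pair
    vel[22] = -40.0  # jitter within min_interval of the first
    events = detect_events(t, vel, np.ones(60, bool), "left")
    # the first crossing is accepted; every rebound within min_interval of it
    # is rejected, so the jitter burst yields exactly one event
    assert [e.kind for e in events] == ["heel_down"]


def test_crossing_spanning_invalid_frames_not_emitted():
    t = np.arange(60) / 15.0
    vel = np.where(t < 2.0, 500.0, -500.0)
    valid = np.ones(60, bool)
    valid[28:32] = False  # the sign change happens inside the gap
    assert detect_events(t, vel, valid, "left") == []


def test_validate_clean_event_set_has_no_anomalies(clean_walk):
    seq, _ = clean_walk
    bilateral = validate_event_sequence(
        detect_side_events(seq, "left"), detect_side_events(seq, "right")
    )
    assert bilateral.anomalies == []


def test_validate_flags_missing_opposite_heel_down():
    left = [
        GaitEvent(0.0, "left", "heel_down"),
        GaitEvent(0.7, "left", "toe_up"),
        GaitEvent(1.2, "left", "heel_down"),
    ]
    bilateral = validate_event_sequence(left, [])
    assert any("no opposite heel_down" in a for a in bilateral.anomalies)


def test_validate_empty_input():
    bilateral = validate_event_sequence([], [])
    assert bilateral.merged == [] and bilateral.anomalies == []


def test_event_config_validation():
    with pytest.raises(ValueError):
        EventDetectionConfig(smooth_window=2)
    with pytest.raises(ValueError):
        EventDetectionConfig(min_interval=0.0)
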