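"""Stride segmentation and per-stride metric recovery."""

import math

import numpy as np
import pytest

import treadgait as tg
from treadgait.com_model import ComTrajectory
from treadgait.gait_events import BilateralEvents, GaitEvent
from treadgait.gait_metrics import (
    StrideRecord,
    belt_speed_estimate,
    com_step_ratio,
    com_stride_ranges,
    compute_strides,
    segment_strides,
    stride_metric_values,
    summarize,
    support_times,
)
from treadgait.joints import JOINT_INDEX

from conftest import make_static_seq


def _schedule(T=1.2, duty=0.6, n_strides=5, offset_right=0.5):
    """Analytic bilateral event schedule (the treadmill timing closed form)."""
    left, right = [], []
    for k in range(n_strides + 1):
        left.append(GaitEvent(k * T, "left", "heel_down"))
        left.append(GaitEvent(k * T + duty * T, "left", "toe_up"))
    for k in range(-1, n_strides + 1):  # k = -1: the right cycle already underway
        hd = (k + offset_right) * T
        if hd >= 0:
            right.append(GaitEvent(hd, "right", "heel_down"))
        if hd + duty * T >= 0:
            right.append(GaitEvent(hd + duty * T, "right", "toe_up"))
    return BilateralEvents(sorted(left), sorted(right), [])


def test_segment_strides_pairs_consecutive_heel_downs():
    bl = _schedule(n_strides=5)
    strides = segment_strides(bl, "left")
    assert len(strides) == 5
    assert all(s.stride_time == pytest.approx(1.2) for s in strides)


def test_fewer_than_two_heel_downs_gives_no_strides():
    bl = BilateralEvents([GaitEvent(0.0, "left", "heel_down")], [], [])
    assert segment_strides(bl, "left") == []


def test_support_times_closed_form_from_duty_factor():
    """duty d, stride T: each double-support component (d-1/2)T, single
    support (1-d)T."""
    T, d = 1.2, 0.6
    bl = _schedule(T=T, duty=d)
    s = segment_strides(bl, "left")[1]
    support_times(s, bl)
    assert not s.excluded
    assert s.ds_lead_in == pytest.approx((d - 0.5) * T, abs=1e-12)
    assert s.ds_lead_out == pytest.approx((d - 0.5) * T, abs=1e-12)
    assert s.single_support_time == pytest.approx((1 - d) * T, abs=1e-12)


def test_duty_half_has_zero_double_support_in_ground_truth():
    _, truth = tg.simulate(tg.SimConfig(duration=20.0, duty_factor=0.5, noise_sd=0.0, seed=0))
    assert truth.strides["left"][0]["double_support_component"] == 0.0
    assert truth.strides["left"][0]["single_support_time"] == pytest.approx(
        0.5 * truth.config.stride_time
    )


def test_support_times_match_hand_computed_event_differences():
    # asymmetric timing: right foot lags 0.45 of the stride, stance 0.62
    bl = _schedule(T=1.0, duty=0.62, offset_right=0.45)
    s = segment_strides(bl, "left")[1]  # stride [1.0, 2.0]
    support_times(s, bl)
    # right toe-up inside: 0.45 + 0.62 = 1.07; right heel-down: 1.45;
    # left toe-up after it: 1.62
    assert s.ds_lead_in == pytest.approx(1.07 - 1.0)
    assert s.single_support_time == pytest.approx(1.45 - 1.07)
    assert s.ds_lead_out == pytest.approx(1.62 - 1.45)


def test_missing_opposite_event_excludes_stride():
    bl = _schedule(n_strides=5)
    victim = next(e for e in bl.right if e.kind == "toe_up" and 1.8 < e.time < 3.0)
    bl.right.remove(victim)  # right toe-up at 2.52
    seq = make_static_seq(n=110)  # static: no gaps
    com = ComTrajectory(seq.timestamps, np.zeros((110, 3)), np.ones(110, bool))
    left = compute_strides(seq, com, bl, "left")
    right = compute_strides(seq, com, bl, "right")
    # only the left stride [2.4, 3.6] and right stride [1.8, 3.0] needed it
    assert [s.excluded for s in left] == [False, False, True, False, False]
    assert [(s.excluded, s.exclude_reason == "missing_event") for s in right][1] == (True, True)
    assert sum(s.excluded for s in left + right) == 2


def test_belt_speed_from_stance_slope(clean_walk):
    seq, truth = clean_walk
    res = tg.analyze_sequence(seq, spectral=False)
    ok = [s for s in res.strides if not s.excluded]
    est = np.mean([s.belt_speed for s in ok])
    assert est == pytest.approx(truth.config.belt_speed, rel=0.02)


def test_belt_speed_zero_for_stationary_foot():
    bl = _schedule(n_strides=2)
    seq = make_static_seq(n=60)
    s = segment_strides(bl, "left")[0]
    assert belt_speed_estimate(seq, s, bl) == pytest.approx(0.0, abs=1e-9)


def test_belt_speed_noise_robustness_median_within_5pct():
    seq, truth = tg.simulate(tg.SimConfig(duration=30.0, noise_sd=5.0, seed=13))
    res = tg.analyze_sequence(seq, spectral=False)
    speeds = [s.belt_speed for s in res.strides if not s.excluded]
    assert len(speeds) >= 20
    assert np.median(speeds) == pytest.approx(truth.config.belt_speed, rel=0.05)


def test_stride_length_is_belt_speed_times_stride_time():
    s = StrideRecord("left", 0.0, 1.2, stride_time=1.2, belt_speed=1000.0)
    assert s.belt_speed * s.stride_time == pytest.approx(1200.0)
    s0 = StrideRecord("left", 0.0, 1.2, stride_time=1.2, belt_speed=0.0)
    assert s0.belt_speed * s0.stride_time == 0.0


def test_stride_length_recovery_within_3pct():
    seq, truth = tg.simulate(
        tg.SimConfig(duration=60.0, belt_speed=1000.0, stride_time=1.1, noise_sd=2.0, seed=21)
    )
    res = tg.analyze_sequence(seq, spectral=False)
    ok = [s for s in res.strides if not s.excluded]
    assert np.mean([s.stride_length for s in ok]) == pytest.approx(1100.0, rel=0.03)


def test_step_width_hand_fixture():
    """Left stance ML mean −70, right +70 → 140 mm."""
    bl = _schedule(n_strides=2)
    seq = make_static_seq(n=60)
    seq.positions[:, JOINT_INDEX["ankle_left"], 0] = -70.0
    seq.positions[:, JOINT_INDEX["ankle_right"], 0] = 70.0
    s = segment_strides(bl, "left")[0]
    assert tg.step_width(seq, s, bl) == pytest.approx(140.0)
    # both feet on the midline
    seq.positions[:, JOINT_INDEX["ankle_right"], 0] = -70.0
    assert tg.step_width(seq, s, bl) == pytest.approx(0.0)


def test_step_width_recovery_noiseless(clean_walk, clean_analysis):
    _, truth = clean_walk
    ok = [s for s in clean_analysis.strides if not s.excluded]
    assert np.mean([s.step_width for s in ok]) == pytest.approx(
        truth.config.step_width, abs=1.0
    )


def test_com_stride_ranges_sine_and_constant():
    fs, T, A = 15.0, 1.2, 30.0
    t = np.arange(int(fs * T) + 1) / fs
    pos = np.zeros((t.size, 3))
    pos[:, 0] = A * np.sin(2 * np.pi * t / T)
    com = ComTrajectory(t, pos, np.ones(t.size, bool))
    s = StrideRecord("left", 0.0, T, stride_time=T)
    width, height, fore_aft = com_stride_ranges(com, s)
    # discrete max-min oracle on the same samples
    sel = (t >= 0) & (t < T)
    assert width == pytest.approx(pos[sel, 0].max() - pos[sel, 0].min(), abs=1e-12)
    assert width <= 2 * A and width >= 2 * A * np.cos(np.pi / (fs * T))
    assert (height, fore_aft) == (0.0, 0.0)
    const = ComTrajectory(t, np.full((t.size, 3), 7.0), np.ones(t.size, bool))
    assert com_stride_ranges(const, s) == (0.0, 0.0, 0.0)


def test_com_stride_ranges_invalid_frame_gives_nan():
    t = np.arange(10) / 15.0
    com = ComTrajectory(t, np.zeros((10, 3)), np.ones(10, bool))
    com.valid[4] = False
    s = StrideRecord("left", 0.0, 0.6, stride_time=0.6)
    assert all(math.isnan(v) for v in com_stride_ranges(com, s))


def test_com_step_ratio_cases():
    assert com_step_ratio(42.0, 140.0) == pytest.approx(0.30)
    assert com_step_ratio(0.0, 140.0) == 0.0
    assert math.isnan(com_step_ratio(42.0, 0.0))


def test_com_step_ratio_from_simulator_geometry():
    seq, _ = tg.simulate(
        tg.SimConfig(duration=40.0, a_ml=25.0, step_width=125.0, noise_sd=0.0, seed=31)
    )
    res = tg.analyze_sequence(seq, spectral=False)
    ok = [s for s in res.strides if not s.excluded]
    ratio = np.mean([s.com_step_ratio for s in ok])
    assert ratio == pytest.approx(2 * 25.0 / 125.0, rel=0.05)


def test_sixty_second_walk_yields_about_fifty_strides():
    seq, _ = tg.simulate(tg.SimConfig(duration=60.0, stride_time=1.2, noise_sd=0.0, seed=41))
    res = tg.analyze_sequence(seq, spectral=False)
    left = [s for s in res.strides if s.side == "left"]
    assert 48 <= len(left) <= 50
    assert all(not s.excluded for s in left)


def test_com_confined_within_step_width_gives_ratio_below_one(clean_analysis):
    values = stride_metric_values(clean_analysis.strides)
    assert all(r < 1.0 for r in values["com_step_ratio"])


def test_stride_time_bookkeeping_closes_over_the_minute(clean_analysis):
    left = [s for s in clean_analysis.strides if s.side == "left" and not s.excluded]
    covered = sum(s.stride_time for s in left)
    span = left[-1].end_heel_down - left[0].start_heel_down
    assert covered == pytest.approx(span, abs=1e-9)


def test_summary_aggregates_only_non_excluded(clean_analysis):
    summary = summarize(clean_analysis.strides)
    n_ok = sum(1 for s in clean_analysis.strides if not s.excluded and s.side == "left")
    mean, sd = summary.metrics["left_stride_time"]
    vals = [
        s.stride_time for s in clean_analysis.strides if s.side == "left" and not s.excluded
    ]
    assert n_ok == len(vals)
    assert mean == pytest.approx(np.mean(vals))
    assert sd == pytest.approx(np.std(vals, ddof=1))
    assert summary.gait_speed == pytest.approx(0.575, rel=0.03)
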