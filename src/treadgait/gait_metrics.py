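"""Stride segmentation and per-stride spatiotemporal / CoM metrics.

A stride runs from one heel-down to the next heel-down of the same foot.
Within each stride the module derives:

* stride time (heel-down to heel-down),
* belt speed, estimated as the (negated) least-squares slope of the stance
  foot's AP position over the central 60 % of stance — on a treadmill the
  planted foot translates backward at exactly belt speed,
* stride length = belt speed × stride time (the treadmill convention),
* single-support time (opposite foot's toe-up to its heel-down) and the two
  double-support components (each heel-down to the opposite foot's next
  toe-up),
* step width = |mean stance ML position, left foot − right foot|,
* per-axis CoM excursion (max − min) over the stride and the CoM-width /
  step-width stability ratio.

A stride missing any constituent event, spanning a residual (>1-frame) gap in
a required joint, or lacking a valid CoM frame is flagged excluded with a
reason; it is reported, never silently dropped, so the quality accounting in
:mod:`treadgait.preprocess` stays consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .com_model import ComTrajectory
from .gait_events import BilateralEvents
from .skeleton_io import SkeletonSequence

OTHER = {"left": "right", "right": "left"}

#: Subject-level metric names (the 13 compared statistically).
METRIC_NAMES = (
    "left_stride_length",
    "left_stride_time",
    "right_stride_length",
    "right_stride_time",
    "left_single_support_time",
    "right_single_support_time",
    "ds_left_to_right",
    "ds_right_to_left",
    "com_fore_aft",
    "com_width",
    "com_height",
    "step_width",
    "com_step_ratio",
)


@dataclass(frozen=True)
class MetricsConfig:
    reference_joint: str = "ankle"  # stance ML / belt-speed reference, per side
    required_joints: tuple[str, ...] = (
        "ankle_left",
        "ankle_right",
        "foot_left",
        "foot_right",
    )
    stance_trim_fraction: float = 0.2  # trimmed from each end for the belt fit


@dataclass
class StrideRecord:
    side: str
    start_heel_down: float
    end_heel_down: float
    stride_time: float
    belt_speed: float = math.nan  # mm/s
    stride_length: float = math.nan  # mm
    single_support_time: float = math.nan  # s
    ds_lead_in: float = math.nan  # s, this heel-down -> opposite toe-up
    ds_lead_out: float = math.nan  # s, opposite heel-down -> own toe-up
    step_width: float = math.nan  # mm
    com_width: float = math.nan  # mm (ML range)
    com_height: float = math.nan  # mm (vertical range)
    com_fore_aft: float = math.nan  # mm (AP range)
    com_step_ratio: float = math.nan
    excluded: bool = False
    exclude_reason: str = ""

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclude_reason = self.exclude_reason or reason


def segment_strides(bilateral: BilateralEvents, side: str) -> list[StrideRecord]:
    """Candidate strides: consecutive same-side heel-down pairs."""
    evs = bilateral.left if side == "left" else bilateral.right
    hds = [e.time for e in evs if e.kind == "heel_down"]
    return [
        StrideRecord(side=side, start_heel_down=t0, end_heel_down=t1, stride_time=t1 - t0)
        for t0, t1 in zip(hds, hds[1:])
    ]


def support_times(stride: StrideRecord, bilateral: BilateralEvents) -> None:
    """Fill single- and double-support components from opposite-foot events.

    With heel-down at phase 0 and duty factor d: the opposite foot is still
    planted until its toe-up, giving a double-support component (d − 0.5)·T;
    the opposite swing (its toe-up to its heel-down) is this foot's
    single-support interval, (1 − d)·T; the opposite heel-down to this foot's
    own toe-up is the second double-support component.  Any missing event
    excludes the stride.
    """
    t0, t1, side = stride.start_heel_down, stride.end_heel_down, stride.side
    opp = OTHER[side]
    opp_tu = bilateral.events_between(t0, t1, opp, "toe_up")
    opp_hd = bilateral.events_between(t0, t1, opp, "heel_down")
    own_tu = bilateral.events_between(t0, t1, side, "toe_up")
    if not opp_tu or not opp_hd or not own_tu:
        stride.exclude("missing_event")
        return
    tu1 = opp_tu[0].time
    hd_opp = next((e.time for e in opp_hd if e.time > tu1), None)
    if hd_opp is None:
        stride.exclude("missing_event")
        return
    own_tu_after = next((e.time for e in own_tu if e.time > hd_opp), None)
    if own_tu_after is None:
        stride.exclude("missing_event")
        return
    stride.ds_lead_in = tu1 - t0
    stride.single_support_time = hd_opp - tu1
    stride.ds_lead_out = own_tu_after - hd_opp


def _stance_interval(stride: StrideRecord, bilateral: BilateralEvents) -> tuple[float, float] | None:
    own_tu = bilateral.events_between(
        stride.start_heel_down, stride.end_heel_down, stride.side, "toe_up"
    )
    if not own_tu:
        return None
    return stride.start_heel_down, own_tu[-1].time


def belt_speed_estimate(
    seq: SkeletonSequence,
    stride: StrideRecord,
    bilateral: BilateralEvents,
    config: MetricsConfig | None = None,
) -> float:
    """Belt speed from the stance foot's backward drift.

    Least-squares slope of the reference joint's AP position over the central
    (1 − 2·trim) portion of stance, negated.  NaN (and stride exclusion by the
    caller) if fewer than 3 valid frames remain.
    """
    config = config or MetricsConfig()
    stance = _stance_interval(stride, bilateral)
    if stance is None:
        return math.nan
    t0, t1 = stance
    trim = config.stance_trim_fraction * (t1 - t0)
    lo, hi = t0 + trim, t1 - trim
    joint = f"{config.reference_joint}_{stride.side}"
    t = seq.timestamps
    sel = (t >= lo) & (t <= hi) & seq.joint_valid(joint)
    if sel.sum() < 3:
        return math.nan
    slope = np.polyfit(t[sel], seq.joint(joint)[sel, 1], 1)[0]
    return float(-slope)


def step_width(
    seq: SkeletonSequence,
    stride: StrideRecord,
    bilateral: BilateralEvents,
    config: MetricsConfig | None = None,
) -> float:
    """|mean stance ML of the left foot − mean stance ML of the right foot|.

    Own-foot stance is heel-down → own toe-up; the opposite foot's stance
    inside the stride starts at its heel-down.
    """
    config = config or MetricsConfig()
    stance = _stance_interval(stride, bilateral)
    opp = OTHER[stride.side]
    opp_hd = bilateral.events_between(stride.start_heel_down, stride.end_heel_down, opp, "heel_down")
    if stance is None or not opp_hd:
        return math.nan
    t = seq.timestamps
    means = {}
    for side, (lo, hi) in (
        (stride.side, stance),
        (opp, (opp_hd[0].time, stride.end_heel_down)),
    ):
        joint = f"{config.reference_joint}_{side}"
        sel = (t >= lo) & (t <= hi) & seq.joint_valid(joint)
        if sel.sum() == 0:
            return math.nan
        means[side] = seq.joint(joint)[sel, 0].mean()
    return float(abs(means["left"] - means["right"]))


def com_stride_ranges(com: ComTrajectory, stride: StrideRecord) -> tuple[float, float, float]:
    """Per-axis max − min of the CoM within [start, end); NaNs if any CoM
    frame in the stride is invalid."""
    t = com.timestamps
    sel = (t >= stride.start_heel_down) & (t < stride.end_heel_down)
    if sel.sum() == 0 or not np.all(com.valid[sel]):
        return (math.nan, math.nan, math.nan)
    p = com.position[sel]
    rng = p.max(axis=0) - p.min(axis=0)
    return (float(rng[0]), float(rng[2]), float(rng[1]))  # width (ML), height (vert), fore-aft (AP)


def com_step_ratio(width: float, step_w: float) -> float:
    """Medial–lateral CoM excursion as a fraction of step width (the CoM-vs-
    base-of-support stability index); undefined for zero step width."""
    if not step_w > 0:
        return math.nan
    return width / step_w


def _has_gap(seq: SkeletonSequence, joints: tuple[str, ...], t0: float, t1: float) -> bool:
    sel = (seq.timestamps >= t0) & (seq.timestamps < t1)
    for j in joints:
        if np.any(~seq.joint_valid(j)[sel]):
            return True
    return False


def compute_strides(
    seq: SkeletonSequence,
    com: ComTrajectory,
    bilateral: BilateralEvents,
    side: str,
    config: MetricsConfig | None = None,
) -> list[StrideRecord]:
    """Segment one side's strides and fill every per-stride metric.

    Exclusion reasons, in the order checked: residual data gap in a required
    joint ("data_gap"), missing constituent event ("missing_event"), stance
    too short for the belt fit ("short_stance"), invalid CoM frame
    ("invalid_com").
    """
    config = config or MetricsConfig()
    strides = segment_strides(bilateral, side)
    for s in strides:
        if _has_gap(seq, config.required_joints, s.start_heel_down, s.end_heel_down):
            s.exclude("data_gap")
            continue
        support_times(s, bilateral)
        if s.excluded:
            continue
        s.belt_speed = belt_speed_estimate(seq, s, bilateral, config)
        if math.isnan(s.belt_speed):
            s.exclude("short_stance")
            continue
        s.stride_length = s.belt_speed * s.stride_time
        s.step_width = step_width(seq, s, bilateral, config)
        if math.isnan(s.step_width):
            s.exclude("missing_event")
            continue
        s.com_width, s.com_height, s.com_fore_aft = com_stride_ranges(com, s)
        if math.isnan(s.com_width):
            s.exclude("invalid_com")
            continue
        s.com_step_ratio = com_step_ratio(s.com_width, s.step_width)
    return strides


@dataclass
class SubjectSummary:
    """Per-metric mean and SD over non-excluded strides, plus stride counts
    and the subject's gait speed (mean belt-speed estimate, m/s)."""

    metrics: dict[str, tuple[float, float]]
    n_strides: dict[str, int]
    n_excluded: dict[str, int]
    gait_speed: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "mean": m, "sd": sd} for k, (m, sd) in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size == 0:
        return (math.nan, math.nan)
    return (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)


def stride_metric_values(strides: list[StrideRecord]) -> dict[str, list[float]]:
    """Per-metric value lists over non-excluded strides (stride-level, for the
    two-session comparison)."""
    ok = [s for s in strides if not s.excluded]
    out: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for s in ok:
        out[f"{s.side}_stride_length"].append(s.stride_length)
        out[f"{s.side}_stride_time"].append(s.stride_time)
        out[f"{s.side}_single_support_time"].append(s.single_support_time)
        # double-support naming: a left stride's lead-in runs from the left
        # heel-down to the right toe-up, i.e. the left-to-right component
        key = "ds_left_to_right" if s.side == "left" else "ds_right_to_left"
        out[key].append(s.ds_lead_in)
        out["com_fore_aft"].append(s.com_fore_aft)
        out["com_width"].append(s.com_width)
        out["com_height"].append(s.com_height)
        out["step_width"].append(s.step_width)
        out["com_step_ratio"].append(s.com_step_ratio)
    return out


def summarize(strides: list[StrideRecord]) -> SubjectSummary:
    values = stride_metric_values(strides)
    ok = [s for s in strides if not s.excluded]
    speeds = [s.belt_speed for s in ok if not math.isnan(s.belt_speed)]
    return SubjectSummary(
        metrics={m: _mean_sd(v) for m, v in values.items()},
        n_strides={
            side: sum(1 for s in strides if s.side == side) for side in ("left", "right")
        },
        n_excluded={
            side: sum(1 for s in strides if s.side == side and s.excluded)
            for side in ("left", "right")
        },
        gait_speed=float(np.mean(speeds)) / 1000.0 if speeds else math.nan,
    )


def strides_to_frame(strides: list[StrideRecord]) -> pd.DataFrame:
    """One row per stride, excluded rows retained with their reason."""
    return pd.DataFrame([vars(s) for s in strides])
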