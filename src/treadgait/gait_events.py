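"""Gait-event detection from anterior–posterior foot velocity.

On a treadmill the planted foot is carried backward at belt speed and swings
forward to re-plant, so its anterior–posterior velocity is negative in stance
and positive in swing.  Heel-down is therefore the forward-to-backward
(+ → −) zero-crossing of the foot's AP velocity, and toe-up the backward-to-
forward (− → +) crossing.  Vertical-position thresholds are avoided entirely:
they are fragile against tracker jitter, whereas the direction reversal is
robust.

Event times are sub-frame: the zero crossing is linearly interpolated between
the bracketing samples.  A minimum-interval debounce and strict heel-down /
toe-up alternation guard against jitter-induced double crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton_io import SkeletonSequence


@dataclass(frozen=True, order=True)
class GaitEvent:
    time: float  # seconds, sub-frame (interpolated)
    side: str = field(compare=False)  # "left" | "right"
    kind: str = field(compare=False)  # "heel_down" | "toe_up"
    frame_before: int = field(compare=False, default=-1)


@dataclass(frozen=True)
class EventDetectionConfig:
    reference_joint_heel_down: str = "ankle"  # resolved per side, e.g. ankle_left
    reference_joint_toe_up: str = "ankle"  # set to "foot" to use the toe point
    smooth_window: int = 3  # centred moving average, frames (odd)
    min_interval: float = 0.3  # debounce between accepted events, seconds

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.min_interval <= 0:
            raise ValueError("min_interval must be > 0")


def _smooth(values: np.ndarray, valid: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred moving average; a smoothed sample is valid only if its full
    window is in range and valid (edge-shrunk windows would bias the
    derivative, so edges are dropped instead)."""
    if window == 1:
        return values.copy(), valid.copy()
    n = values.shape[0]
    half = window // 2
    out = np.full(n, np.nan)
    out_valid = np.zeros(n, dtype=bool)
    for i in range(half, n - half):
        lo, hi = i - half, i + half + 1
        if np.all(valid[lo:hi]):
            out[i] = values[lo:hi].mean()
            out_valid[i] = True
    return out, out_valid


def ap_velocity(
    seq: SkeletonSequence, joint: str, config: EventDetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AP velocity (mm/s) of one joint: smoothed position, central-difference
    derivative on actual timestamps.  Returns (times, velocity, valid);
    invalid samples propagate invalidity.  Fewer than 3 valid frames yields an
    all-empty series.
    """
    config = config or EventDetectionConfig()
    t = seq.timestamps
    n = seq.frame_count
    if int(seq.joint_valid(joint).sum()) < 3 or n < 3:
        return np.empty(0), np.empty(0), np.empty(0, dtype=bool)
    y, yv = _smooth(seq.joint(joint)[:, 1], seq.joint_valid(joint), config.smooth_window)
    vel = np.full(n, np.nan)
    vv = np.zeros(n, dtype=bool)
    # interior: central difference on timestamps
    ok = yv[:-2] & yv[2:]
    i = np.arange(1, n - 1)[ok]
    vel[i] = (y[i + 1] - y[i - 1]) / (t[i + 1] - t[i - 1])
    vv[i] = True
    # one-sided ends
    if yv[0] and yv[1]:
        vel[0] = (y[1] - y[0]) / (t[1] - t[0])
        vv[0] = True
    if yv[-1] and yv[-2]:
        vel[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
        vv[-1] = True
    return t.copy(), vel, vv


def _refine_crossing(
    t_coarse: float,
    i: int,
    kind: str,
    times: np.ndarray,
    raw_pos: np.ndarray,
    raw_valid: np.ndarray,
) -> float:
    """Sharpen a crossing time on raw first-difference (midpoint) velocities.

    The smoothed velocity used for detection spans ±2 frames, so its
    crossing inherits a shift from any velocity asymmetry around the event
    (stance and swing speeds differ whenever the duty factor is not 0.5).  On
    the raw AP position the event is a corner between the backward stance
    drift and the forward swing arc.  The unsmoothed forward differences
    localise the sign flip to a two-interval window; within it exactly one
    frame interval contains the corner, and that interval's average velocity
    is a duration-weighted blend of the pre-event velocity A and post-event
    velocity B read from the adjacent pure intervals:

        w_mixed = (A (t_c - t_k) + B (t_{k+1} - t_c)) / dt.

    Solving the blend for the corner time t_c is exact for a sawtooth at any
    event phase within the frame.  Both candidate intervals are tried and the
    solution lying inside its own interval wins.  Falls back to a plain
    midpoint-velocity interpolation, then to the coarse time, when invalid
    samples or noise defeat the model.
    """
    n = len(times)
    if n < 2:
        return t_coarse
    half = float(np.max(np.diff(times))) / 2.0

    def w_at(k: int) -> float | None:
        if 0 <= k < n - 1 and raw_valid[k] and raw_valid[k + 1]:
            return float((raw_pos[k + 1] - raw_pos[k]) / (times[k + 1] - times[k]))
        return None

    want = -1.0 if kind == "heel_down" else 1.0  # velocity sign after the crossing
    flips = []  # (closeness to coarse, midpoint-interp time, first interval index)
    for a in range(max(0, i - 3), min(n - 2, i + 3)):
        w0, w1 = w_at(a), w_at(a + 1)
        if w0 is None or w1 is None or w0 == w1:
            continue
        if np.sign(w0) == -want and np.sign(w1) == want:
            m0 = (times[a] + times[a + 1]) / 2.0
            m1 = (times[a + 1] + times[a + 2]) / 2.0
            t_mid = m0 + (m1 - m0) * w0 / (w0 - w1)
            flips.append((abs(t_mid - t_coarse), t_mid, a))
    if not flips:
        return t_coarse
    _, t_mid, a = min(flips)

    candidates = []
    for k, pre_k, post_k in ((a, a - 1, a + 1), (a + 1, a, a + 2)):
        w_mix, w_pre, w_post = w_at(k), w_at(pre_k), w_at(post_k)
        if w_mix is None or w_pre is None or w_post is None or w_pre == w_post:
            continue
        dt_k = times[k + 1] - times[k]
        t_c = (w_pre * times[k] - w_post * times[k + 1] + w_mix * dt_k) / (w_pre - w_post)
        if times[k] - half <= t_c <= times[k + 1] + half:
            candidates.append((abs(t_c - t_mid), t_c))
    return float(min(candidates)[1]) if candidates else float(t_mid)


def detect_events(
    times: np.ndarray,
    vel: np.ndarray,
    valid: np.ndarray,
    side: str,
    config: EventDetectionConfig | None = None,
    raw_pos: np.ndarray | None = None,
    raw_valid: np.ndarray | None = None,
) -> list[GaitEvent]:
    """Zero-crossing gait events from one foot's AP velocity series.

    + → − crossings become heel_down, − → + become toe_up; the event time is
    the linear interpolation of the crossing between the bracketing samples
    (refined on the raw AP positions when they are supplied — see
    :func:`_refine_crossing`).  A crossing is only considered between
    *adjacent* valid samples (a crossing spanning invalid frames is never
    fabricated), crossings within ``min_interval`` of the last accepted event
    are debounced, and the output strictly alternates kinds.
    """
    config = config or EventDetectionConfig()
    n = len(vel)
    if n < 2:
        return []
    # Sign with zero samples inheriting the previous non-zero sign, so an
    # exact zero touch does not fabricate a double crossing.
    sign = np.sign(vel)
    last = 0.0
    for i in range(n):
        if not valid[i]:
            last = 0.0
            continue
        if sign[i] == 0.0:
            sign[i] = last
        last = sign[i]

    events: list[GaitEvent] = []
    last_kind: str | None = None
    last_time = -np.inf
    for i in range(n - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        s0, s1 = sign[i], sign[i + 1]
        if s0 == 0.0 or s1 == 0.0 or s0 == s1:
            continue
        kind = "heel_down" if s0 > 0 else "toe_up"
        v0, v1 = vel[i], vel[i + 1]
        frac = v0 / (v0 - v1) if v0 != v1 else 0.5
        t_ev = times[i] + frac * (times[i + 1] - times[i])
        if raw_pos is not None and raw_valid is not None:
            t_ev = _refine_crossing(t_ev, i, kind, times, raw_pos, raw_valid)
        if t_ev - last_time < config.min_interval:
            continue
        if kind == last_kind:
            continue  # alternation: a debounced partner left an orphan crossing
        events.append(GaitEvent(time=float(t_ev), side=side, kind=kind, frame_before=i))
        last_kind = kind
        last_time = t_ev
    return events


def detect_side_events(
    seq: SkeletonSequence, side: str, config: EventDetectionConfig | None = None
) -> list[GaitEvent]:
    """Detect heel-down and toe-up for one side from the configured joints.

    With distinct reference joints per event kind, each joint's crossings are
    detected independently and the union re-filtered for alternation.
    """
    config = config or EventDetectionConfig()
    joints = {
        "heel_down": f"{config.reference_joint_heel_down}_{side}",
        "toe_up": f"{config.reference_joint_toe_up}_{side}",
    }
    def _detect(joint: str) -> list[GaitEvent]:
        t, v, vv = ap_velocity(seq, joint, config)
        if t.size == 0:
            return []
        return detect_events(
            t, v, vv, side, config,
            raw_pos=seq.joint(joint)[:, 1], raw_valid=seq.joint_valid(joint),
        )

    if joints["heel_down"] == joints["toe_up"]:
        return _detect(joints["heel_down"])
    merged: list[GaitEvent] = []
    for kind, joint in joints.items():
        merged += [e for e in _detect(joint) if e.kind == kind]
    merged.sort()
    out: list[GaitEvent] = []
    for e in merged:
        if out and e.kind == out[-1].kind:
            continue
        out.append(e)
    return out


@dataclass
class BilateralEvents:
    """Validated bilateral event sequence with physiological-order anomalies."""

    left: list[GaitEvent]
    right: list[GaitEvent]
    anomalies: list[str]

    @property
    def merged(self) -> list[GaitEvent]:
        return sorted(self.left + self.right)

    def events_between(self, t0: float, t1: float, side: str, kind: str) -> list[GaitEvent]:
        src = self.left if side == "left" else self.right
        return [e for e in src if kind == e.kind and t0 < e.time < t1]


def validate_event_sequence(
    events_left: list[GaitEvent], events_right: list[GaitEvent]
) -> BilateralEvents:
    """Merge both sides and check physiological ordering.

    Per-side alternation is asserted (the detector guarantees it); bilateral
    anomalies — e.g. two same-side heel-downs with no opposite-side heel-down
    between them, implying a flight phase or a missed event — are recorded as
    flags, never exceptions: strides lacking a constituent event are excluded
    downstream, not fabricated.
    """
    anomalies: list[str] = []
    for side, evs in (("left", events_left), ("right", events_right)):
        for a, b in zip(evs, evs[1:]):
            if b.time <= a.time:
                anomalies.append(f"{side}: events out of order at t={b.time:.3f}")
            if a.kind == b.kind:
                anomalies.append(f"{side}: consecutive {a.kind} at t={b.time:.3f}")
    hd_left = [e.time for e in events_left if e.kind == "heel_down"]
    hd_right = [e.time for e in events_right if e.kind == "heel_down"]
    for side, own, other in (("left", hd_left, hd_right), ("right", hd_right, hd_left)):
        other_arr = np.asarray(other)
        for t0, t1 in zip(own, own[1:]):
            if not np.any((other_arr > t0) & (other_arr < t1)):
                anomalies.append(
                    f"{side}: no opposite heel_down inside stride [{t0:.3f}, {t1:.3f}]"
                )
    return BilateralEvents(list(events_left), list(events_right), anomalies)
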