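"""Seeded kinematic treadmill-walker simulator with exact ground truth.

The simulator emulates the statistical structure the pipeline assumes, not
physiological detail: during stance a foot is carried backward at belt speed,
during swing it returns forward along a smooth raised-cosine profile (the
sawtooth fore–aft pattern of treadmill feet), with a raised-cosine vertical
clearance and a constant medial–lateral offset of ± step_width/2.  The pelvis
and everything above it ride on sinusoidal whole-body drivers: medial–lateral
at stride frequency 1/T, vertical and fore–aft at step frequency 2/T.  The
remaining joints hang off the pelvis and feet by fixed offsets scaled to
stature, so every joint of the 14-segment anthropometric model exists.

Because the kinematic tree is linear in the driver, the driver gain onto the
whole-body CoM is exact and is compensated, so the simulated CoM
medial–lateral amplitude equals ``a_ml`` by construction.  Vertical and
fore–aft CoM additionally carry genuine leg-swing contributions, so their
ground-truth per-stride ranges are taken from the noiseless CoM evaluated at
the sampled frames rather than from a sinusoid formula.

Ground truth is closed-form wherever a closed form exists: heel-down /
toe-up schedules, stride time T, stride length belt_speed·T, step width,
single support (1 − d)·T and each double-support component (d − 0.5)·T for
duty factor d.  Sensor degradation — isotropic Gaussian noise and frame
dropouts with a configurable gap-length distribution — is applied last, from
independent seeded streams, and every injected gap is ledgered.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .com_model import ComTrajectory, com_trajectory, default_table
from .joints import JOINT_INDEX, N_JOINTS
from .skeleton_io import SkeletonSequence, write_skeleton


@dataclass(frozen=True)
class SimConfig:
    duration: float = 180.0  # s (a ~3-minute steady-walking recording)
    fs: float = 15.0  # Hz
    belt_speed: float = 575.0  # mm/s
    stride_time: float = 1.22  # s  (ML CoM dominant = 1/T ≈ 0.82 Hz)
    duty_factor: float = 0.6  # stance fraction of stride
    step_width: float = 140.0  # mm between stance-foot ML means
    a_ml: float = 24.0  # mm: CoM ML amplitude (per-stride width = 2·a_ml)
    a_vert: float = 14.0  # mm: vertical driver amplitude
    a_ap: float = 16.5  # mm: fore-aft driver amplitude
    vert_phase: float = -math.pi / 2 + 0.5  # rad: vertical minima near double support,
    # offset so the ML-vs-vertical Lissajous is a proper figure-eight, not degenerate
    ap_phase: float = math.pi / 2 + 0.6  # rad
    body_scale: float = 1700.0  # stature, mm; drives all fixed segment offsets
    phase_offset_right: float = 0.5  # right heel-down lag, fraction of stride
    foot_clearance: float = 50.0  # mm swing clearance
    arm_swing: float = 0.0  # mm AP arm-swing amplitude (off by default)
    noise_sd: float = 2.0  # mm isotropic Gaussian sensor noise
    dropout_prob: float = 0.0  # per frame-joint gap-start probability
    dropout_gap_dist: tuple[tuple[int, float], ...] = ((1, 1.0),)  # length -> prob
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.duty_factor < 1.0:
            raise ValueError(f"duty_factor must be in [0.5, 1), got {self.duty_factor}")
        if self.fs <= 2.0 / self.stride_time:
            raise ValueError("fs must exceed 2/stride_time to resolve the gait cycle")
        for name in ("a_ml", "a_vert", "a_ap", "noise_sd", "foot_clearance", "step_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.belt_speed < 0:
            raise ValueError("belt_speed must be >= 0")
        total = sum(p for _, p in self.dropout_gap_dist)
        if self.dropout_prob > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("dropout_gap_dist probabilities must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "dropout_gap_dist" in d and isinstance(d["dropout_gap_dist"], dict):
            d["dropout_gap_dist"] = tuple(
                (int(k), float(v)) for k, v in d["dropout_gap_dist"].items()
            )
        return cls(**d)


@dataclass
class SyntheticGroundTruth:
    """True events, per-stride metrics and the injected-dropout ledger."""

    config: SimConfig
    events: dict[str, dict[str, np.ndarray]]  # side -> kind -> times
    strides: dict[str, list[dict]]  # side -> list of per-stride truth dicts
    dropout_ledger: list[tuple[str, int, int]]  # (joint, start_frame, length)
    com_noiseless: ComTrajectory = field(repr=False, default=None)  # type: ignore[assignment]

    def true_events(self, side: str, kind: str) -> np.ndarray:
        return self.events[side][kind]

    def to_json(self, path) -> None:
        doc = {
            "config": {
                **asdict(self.config),
                "dropout_gap_dist": {str(k): v for k, v in self.config.dropout_gap_dist},
            },
            "events": {
                s: {k: v.tolist() for k, v in kinds.items()} for s, kinds in self.events.items()
            },
            "strides": self.strides,
            "dropout_ledger": [list(e) for e in self.dropout_ledger],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _foot_tracks(t: np.ndarray, offset: float, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(AP, vertical-clearance) tracks of one foot's sawtooth cycle.

    Stance: linear backward drift at belt speed.  Swing: forward return whose
    velocity is belt + (v_peak − belt)·sin⁷(πu) — it leaves and lands at
    exactly +belt speed, with flat velocity shoulders around the corners, so
    the fore–aft velocity flips sign symmetrically (−belt ↔ +belt) at
    heel-down and toe-up and stays near-constant for the adjacent frames.
    The sharp sign flip is what makes sub-frame zero-crossing interpolation
    well conditioned; a swing profile that eases in/out of zero velocity
    would smear the crossings over several low-velocity frames.
    """
    T, d = cfg.stride_time, cfg.duty_factor
    t_sw = (1.0 - d) * T
    amp = cfg.belt_speed * d * T  # total backward excursion during stance
    tau = np.mod(t - offset, T)
    stance = tau < d * T
    u = np.clip((tau - d * T) / t_sw, 0.0, 1.0)  # swing progress

    # integral of sin^7(pi s) from 0 to u, via d/dx[G] = sin^7 x with
    # G(x) = -cos x + cos^3 x - (3/5) cos^5 x + (1/7) cos^7 x
    def g7(x: np.ndarray) -> np.ndarray:
        c = np.cos(x)
        return -c + c**3 - 0.6 * c**5 + c**7 / 7.0

    f_u = (g7(np.pi * u) - g7(np.zeros_like(u))) / np.pi
    f_total = 32.0 / (35.0 * np.pi)  # F(1): full sin^7 integral
    v_extra = (amp - cfg.belt_speed * t_sw) / (t_sw * f_total)  # v_peak − belt
    y_swing = -amp / 2.0 + cfg.belt_speed * u * t_sw + v_extra * t_sw * f_u
    y = np.where(stance, amp / 2.0 - cfg.belt_speed * tau, y_swing)
    z = np.where(stance, 0.0, cfg.foot_clearance * (1 - np.cos(2 * np.pi * u)) / 2.0)
    return y, z


def _build_positions(t: np.ndarray, o: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Noiseless (n, 20, 3) joint positions; ``o`` is the (n, 3) body driver."""
    n = len(t)
    s = cfg.body_scale / 1700.0
    pos = np.zeros((n, N_JOINTS, 3))

    def put(name: str, arr: np.ndarray) -> None:
        pos[:, JOINT_INDEX[name], :] = arr

    ankles = {}
    for side, sgn, off in (("left", -1.0, 0.0), ("right", 1.0, cfg.phase_offset_right * cfg.stride_time)):
        y, z = _foot_tracks(t, off, cfg)
        ankle = np.column_stack([np.full(n, sgn * cfg.step_width / 2.0), y, 80.0 * s + z])
        foot = ankle + np.array([0.0, 120.0 * s, -40.0 * s])
        put(f"ankle_{side}", ankle)
        put(f"foot_{side}", foot)
        ankles[side] = ankle

    pelvis = np.array([0.0, 0.0, 930.0 * s]) + o
    put("pelvis", pelvis)
    put("spine_chest", pelvis + np.array([0.0, 10.0 * s, 310.0 * s]))
    put("neck", pelvis + np.array([0.0, 15.0 * s, 520.0 * s]))
    put("head", pelvis + np.array([0.0, 15.0 * s, 670.0 * s]))
    phase = 2 * np.pi * t / cfg.stride_time
    for side, sgn, swing_sign in (("left", -1.0, 1.0), ("right", 1.0, -1.0)):
        hip = pelvis + np.array([sgn * 90.0 * s, 0.0, -30.0 * s])
        put(f"hip_{side}", hip)
        knee = 0.5 * (hip + ankles[side]) + np.array([0.0, 30.0 * s, 0.0])
        put(f"knee_{side}", knee)
        shoulder = pelvis + np.array([sgn * 190.0 * s, 10.0 * s, 370.0 * s])
        put(f"shoulder_{side}", shoulder)
        swing = swing_sign * cfg.arm_swing * np.sin(phase)
        elbow = shoulder + np.array([sgn * 20.0 * s, 20.0 * s, -280.0 * s])
        elbow = elbow + np.column_stack([np.zeros(n), swing, np.zeros(n)])
        put(f"elbow_{side}", elbow)
        wrist = elbow + np.array([0.0, 30.0 * s, -240.0 * s])
        put(f"wrist_{side}", wrist)
        put(f"hand_tip_{side}", wrist + np.array([0.0, 20.0 * s, -80.0 * s]))
    return pos


def _driver_gain(cfg: SimConfig) -> np.ndarray:
    """Exact per-axis gain of the body driver onto the whole-body CoM.

    The joint layout is affine in the driver, so the gain is the CoM
    difference between a unit-driver frame and a zero-driver frame.
    """
    t = np.zeros(1)
    table = default_table()
    p0 = _build_positions(t, np.zeros((1, 3)), cfg)
    p1 = _build_positions(t, np.ones((1, 3)), cfg)
    from .com_model import body_com

    return body_com(p1[0], table) - body_com(p0[0], table)


def _event_schedule(cfg: SimConfig) -> dict[str, dict[str, np.ndarray]]:
    T, d = cfg.stride_time, cfg.duty_factor
    out: dict[str, dict[str, np.ndarray]] = {}
    for side, off in (("left", 0.0), ("right", cfg.phase_offset_right * T)):
        hd = np.arange(off, cfg.duration, T)
        tu = hd + d * T
        out[side] = {"heel_down": hd, "toe_up": tu[tu < cfg.duration]}
    return out


def simulate(config: SimConfig | None = None) -> tuple[SkeletonSequence, SyntheticGroundTruth]:
    """Generate one treadmill walk; deterministic for a fixed seed."""
    cfg = config or SimConfig()
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    gain = _driver_gain(cfg)
    T = cfg.stride_time

    def drivers(tt: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [
                (cfg.a_ml / gain[0]) * np.sin(2 * np.pi * tt / T),
                (cfg.a_ap / gain[1]) * np.sin(4 * np.pi * tt / T + cfg.ap_phase),
                (cfg.a_vert / gain[2]) * np.sin(4 * np.pi * tt / T + cfg.vert_phase),
            ]
        )

    pos = _build_positions(t, drivers(t), cfg)

    clean = SkeletonSequence(t, pos, np.ones((n, N_JOINTS), dtype=bool), sample_rate_hz=cfg.fs)
    com_clean = com_trajectory(clean)

    # ground-truth CoM ranges come from the continuous noiseless model,
    # evaluated on a grid dense enough (10x) that peak clipping is negligible
    dense = 10
    td = np.arange(n * dense) / (cfg.fs * dense)
    pos_d = _build_positions(td, drivers(td), cfg)
    com_d = com_trajectory(
        SkeletonSequence(td, pos_d, np.ones((len(td), N_JOINTS), dtype=bool), sample_rate_hz=cfg.fs * dense)
    )

    events = _event_schedule(cfg)
    strides: dict[str, list[dict]] = {}
    for side in ("left", "right"):
        hd = events[side]["heel_down"]
        recs = []
        for t0, t1 in zip(hd, hd[1:]):
            sel = (td >= t0) & (td < t1)
            p = com_d.position[sel]
            rng = p.max(axis=0) - p.min(axis=0)
            recs.append(
                {
                    "start": float(t0),
                    "end": float(t1),
                    "stride_time": float(T),
                    "stride_length": float(cfg.belt_speed * T),
                    "step_width": float(cfg.step_width),
                    "single_support_time": float((1.0 - cfg.duty_factor) * T),
                    "double_support_component": float((cfg.duty_factor - 0.5) * T),
                    "com_width": float(rng[0]),
                    "com_height": float(rng[2]),
                    "com_fore_aft": float(rng[1]),
                }
            )
        strides[side] = recs

    rng_noise, rng_drop = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    noisy = pos + (rng_noise.normal(0.0, cfg.noise_sd, pos.shape) if cfg.noise_sd > 0 else 0.0)

    valid = np.ones((n, N_JOINTS), dtype=bool)
    ledger: list[tuple[str, int, int]] = []
    if cfg.dropout_prob > 0:
        lengths = np.array([k for k, _ in cfg.dropout_gap_dist])
        probs = np.array([p for _, p in cfg.dropout_gap_dist])
        starts = rng_drop.random((n, N_JOINTS)) < cfg.dropout_prob
        joint_names = {v: k for k, v in JOINT_INDEX.items()}
        for i, j in zip(*np.nonzero(starts)):
            length = int(rng_drop.choice(lengths, p=probs))
            length = min(length, n - i)
            # keep injected gaps non-adjacent per joint so each realises its
            # drawn length exactly (and the ledger matches the data)
            lo, hi = max(0, i - 1), min(n, i + length + 1)
            if not valid[lo:hi, j].all():
                continue
            valid[i : i + length, j] = False
            ledger.append((joint_names[int(j)], int(i), length))

    seq = SkeletonSequence(t, noisy, valid, sample_rate_hz=cfg.fs)
    truth = SyntheticGroundTruth(
        config=cfg, events=events, strides=strides, dropout_ledger=ledger, com_noiseless=com_clean
    )
    return seq, truth


#: Fixture-suite configurations: named study conditions used across the tests.
FIXTURE_CONFIGS: dict[str, SimConfig] = {
    "clean_walk": SimConfig(duration=60.0, noise_sd=0.0, seed=101),
    "noisy_walk": SimConfig(duration=60.0, noise_sd=3.0, seed=102),
    "gappy_walk": SimConfig(
        duration=60.0,
        noise_sd=2.0,
        dropout_prob=0.01,
        dropout_gap_dist=((1, 0.5), (2, 0.3), (3, 0.2)),
        seed=103,
    ),
    "asymmetric_walk": SimConfig(
        duration=60.0, phase_offset_right=0.44, duty_factor=0.62, noise_sd=1.0, seed=104
    ),
    "stopped_belt": SimConfig(duration=30.0, belt_speed=0.0, noise_sd=0.0, seed=105),
    "pregnancy_session1": SimConfig(duration=90.0, noise_sd=2.0, seed=106),
    "pregnancy_session2": SimConfig(
        duration=90.0, a_ml=30.0, a_vert=16.0, a_ap=15.0, step_width=150.0, noise_sd=2.0, seed=107
    ),
}


def make_fixture_suite(out_dir) -> dict[str, str]:
    """Write the versioned fixture set (skeleton CSVs + ground-truth JSONs)
    and a sha256 manifest; regenerating from the fixed seeds reproduces the
    manifest bit-for-bit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, cfg in FIXTURE_CONFIGS.items():
        seq, truth = simulate(cfg)
        csv_path = out / f"{name}.csv"
        gt_path = out / f"{name}.truth.json"
        write_skeleton(seq, csv_path, format="csv")
        truth.to_json(gt_path)
        for p in (csv_path, gt_path):
            manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def two_session_pair(seed: int = 106) -> tuple[
    tuple[SkeletonSequence, SyntheticGroundTruth], tuple[SkeletonSequence, SyntheticGroundTruth]
]:
    """A within-subject pair with raised ML amplitude and wider steps in
    session 2 (the pregnancy-style follow-up condition)."""
    c1 = replace(FIXTURE_CONFIGS["pregnancy_session1"], seed=seed)
    c2 = replace(FIXTURE_CONFIGS["pregnancy_session2"], seed=seed + 1)
    return simulate(c1), simulate(c2)
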