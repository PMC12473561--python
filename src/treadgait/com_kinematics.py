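"""Stride-phase normalisation, trajectory averaging and spectral analysis of
the whole-body CoM.

Strides are resampled onto a common phase grid (0 = heel-down, 1 = next
same-side heel-down; 101 points by the gait-analysis convention) and
mean-centred per axis so trajectories from strides of different duration can
be averaged.  The Fourier analysis runs on the complete recording: during
steady walking the medial–lateral CoM oscillates once per stride while the
vertical and fore–aft components oscillate once per *step* (twice per
stride), so the dominant ML frequency sits at half the vertical/AP one and
the phase-aligned ML-vs-vertical projection traces the characteristic
figure-eight ("bowtie").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .com_model import ComTrajectory
from .gait_metrics import StrideRecord

AXIS_INDEX = {"ml": 0, "ap": 1, "vert": 2}


@dataclass
class PhaseNormalizedStride:
    phase_grid: np.ndarray  # N points in [0, 1]
    values: np.ndarray  # (N, 3) mm, per-axis stride-mean-centred, canonical order
    source: tuple[str, float]  # (side, start_heel_down) of the source stride


def normalize_strides(
    com: ComTrajectory, strides: list[StrideRecord], n_phase: int = 101
) -> list[PhaseNormalizedStride]:
    """Linear-in-time resampling of each stride's CoM onto the phase grid.

    Only non-excluded strides with valid CoM throughout and at least 4 frames
    are used; shorter strides are skipped with a warning.
    """
    grid = np.linspace(0.0, 1.0, n_phase)
    t = com.timestamps
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    out: list[PhaseNormalizedStride] = []
    for s in strides:
        if s.excluded:
            continue
        inside = (t >= s.start_heel_down) & (t <= s.end_heel_down)
        if inside.sum() < 4:
            warnings.warn(
                f"stride at t={s.start_heel_down:.3f}s has <4 frames; skipped", stacklevel=2
            )
            continue
        if not np.all(com.valid[inside]):
            continue
        # include one valid frame beyond each boundary so the resampling never
        # clamps at a float-rounded stride edge
        sel = (t >= s.start_heel_down - dt) & (t <= s.end_heel_down + dt) & com.valid
        ts = s.start_heel_down + grid * (s.end_heel_down - s.start_heel_down)
        vals = np.column_stack(
            [np.interp(ts, t[sel], com.position[sel, k]) for k in range(3)]
        )
        vals -= vals.mean(axis=0)
        out.append(PhaseNormalizedStride(grid.copy(), vals, (s.side, s.start_heel_down)))
    return out


def mean_trajectory(normed: list[PhaseNormalizedStride]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD across strides at each phase point, per axis."""
    if not normed:
        raise ValueError("no normalized strides to average")
    stack = np.stack([p.values for p in normed])  # (k, N, 3)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    return mean, sd


@dataclass
class SpectralSummary:
    dominant_hz: dict[str, float]  # per axis (ml, ap, vert)
    frequencies: np.ndarray
    magnitudes: dict[str, np.ndarray]
    ml_to_vertical_frequency_ratio: float


def _longest_valid_run(valid: np.ndarray) -> slice:
    best = slice(0, 0)
    i, n = 0, len(valid)
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            if j - i > best.stop - best.start:
                best = slice(i, j)
            i = j
        else:
            i += 1
    return best


def dominant_frequency(
    com: ComTrajectory, axis: str, f_min: float = 0.3, min_duration: float = 10.0
) -> float:
    """Dominant frequency (Hz) of one CoM axis over the longest contiguous
    valid run.

    The series is mean-removed (and, for the AP axis, linearly detrended to
    kill any slow drift along the belt); the dominant frequency is the
    magnitude-spectrum peak above ``f_min``, which excludes DC and residual
    drift.  Records shorter than ``min_duration`` are refused: the frequency
    resolution (1/duration) would be too coarse to be meaningful.
    """
    if axis not in AXIS_INDEX:
        raise ValueError(f"axis must be one of {sorted(AXIS_INDEX)}, got {axis!r}")
    run = _longest_valid_run(com.valid)
    t = com.timestamps[run]
    if len(t) < 2 or (t[-1] - t[0]) < min_duration:
        raise ValueError(
            f"need at least {min_duration:.0f}s of contiguous valid CoM for a spectrum"
        )
    x = com.position[run, AXIS_INDEX[axis]].astype(float)
    x = detrend(x, type="linear") if axis == "ap" else x - x.mean()
    dt = float(np.mean(np.diff(t)))
    freqs = np.fft.rfftfreq(len(x), d=dt)
    mags = np.abs(np.fft.rfft(x))
    band = freqs >= f_min
    if not np.any(band):
        raise ValueError("no spectral bins above f_min; record too short")
    k = int(np.argmax(mags[band]))
    return float(freqs[band][k])


def spectral_summary(com: ComTrajectory, f_min: float = 0.3) -> SpectralSummary:
    """Per-axis magnitude spectra, dominant frequencies, and the ML/vertical
    dominant-frequency ratio (≈ 0.5 in steady gait)."""
    run = _longest_valid_run(com.valid)
    t = com.timestamps[run]
    dt = float(np.mean(np.diff(t)))
    freqs = np.fft.rfftfreq(run.stop - run.start, d=dt)
    mags = {}
    dom = {}
    for axis, k in AXIS_INDEX.items():
        x = com.position[run, k].astype(float)
        x = detrend(x, type="linear") if axis == "ap" else x - x.mean()
        mags[axis] = np.abs(np.fft.rfft(x))
        dom[axis] = dominant_frequency(com, axis, f_min=f_min)
    return SpectralSummary(
        dominant_hz=dom,
        frequencies=freqs,
        magnitudes=mags,
        ml_to_vertical_frequency_ratio=dom["ml"] / dom["vert"],
    )


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper (transversal) intersection of open segments p1p2 and p3p4."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def count_self_intersections(curve: np.ndarray, closed: bool = True) -> int:
    """Transversal self-intersections of a polyline by brute-force pairwise
    segment tests (adjacent segments skipped)."""
    pts = np.asarray(curve, dtype=float)
    if closed and not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    m = len(pts) - 1
    count = 0
    for i in range(m):
        for j in range(i + 2, m):
            if closed and i == 0 and j == m - 1:
                continue  # first and last segments are adjacent on a closed curve
            if _segments_intersect(pts[i], pts[i + 1], pts[j], pts[j + 1]):
                count += 1
    return count


@dataclass
class BowtieProjection:
    ml_vs_vert: np.ndarray  # (N, 2) mean curve
    ml_vs_ap: np.ndarray
    self_intersections_vert: int
    self_intersections_ap: int


def bowtie_projection(normed: list[PhaseNormalizedStride]) -> BowtieProjection:
    """Phase-aligned 2-D projections of the mean stride (ML vs vertical and
    ML vs fore–aft) with their self-intersection counts.

    Because ML runs at stride frequency and vertical/AP at step frequency
    (a 1:2 Lissajous relationship), the mean curve crosses itself at least
    once — the figure-eight signature of steady gait.
    """
    mean, _ = mean_trajectory(normed)
    ml_vert = mean[:, [0, 2]]
    ml_ap = mean[:, [0, 1]]
    return BowtieProjection(
        ml_vs_vert=ml_vert,
        ml_vs_ap=ml_ap,
        self_intersections_vert=count_self_intersections(ml_vert),
        self_intersections_ap=count_self_intersections(ml_ap),
    )
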