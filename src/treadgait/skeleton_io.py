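"""Joint time-series containers and readers/writers.

A :class:`SkeletonSequence` holds a timestamped series of 3-D positions
(millimetres) for the 20 canonical joints with a per-frame, per-joint validity
mask.  Two flat text dialects are supported:

* CSV — one row per frame, columns ``t`` then ``<joint>_{x,y,z}``; a blank
  cell marks an invalid sample.
* JSON — ``{"sample_rate_hz": ..., "frames": [{"t": ..., "joints":
  {"head": [x, y, z] | null, ...}}, ...]}``.

Device axis layouts vary, so readers accept an :class:`AxisConfig` that maps
source axes onto the canonical anatomical frame: x = medial–lateral,
y = anterior–posterior (anterior positive), z = vertical (up positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .joints import CANONICAL_JOINTS, JOINT_INDEX, N_JOINTS, joint_index


class SkeletonFormatError(ValueError):
    """The file does not parse in the declared dialect."""


class SkeletonDataError(ValueError):
    """The file parses but violates a data invariant (e.g. timestamps)."""


_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class AxisConfig:
    """Mapping from device axes to the canonical anatomical frame.

    Each selector names a source axis, optionally sign-flipped, e.g. ``"-z"``.
    ``anterior_positive`` states whether the (signed) source AP axis already
    points in the direction of progression; if False its sign is flipped once
    more so that canonical y is always anterior-positive.
    """

    ml_axis: str = "x"
    ap_axis: str = "y"
    vert_axis: str = "z"
    anterior_positive: bool = True

    def __post_init__(self) -> None:
        names = [self._parse(a)[0] for a in (self.ml_axis, self.ap_axis, self.vert_axis)]
        if len(set(names)) != 3:
            raise ValueError(f"axis selectors must name three distinct source axes, got {names}")

    @staticmethod
    def _parse(selector: str) -> tuple[int, float]:
        s = selector.strip().lower()
        sign = 1.0
        if s.startswith("-"):
            sign, s = -1.0, s[1:]
        elif s.startswith("+"):
            s = s[1:]
        if s not in _AXES:
            raise ValueError(f"axis selector must be one of x, y, z (optionally signed), got {selector!r}")
        return _AXES[s], sign

    def permutation(self) -> tuple[np.ndarray, np.ndarray]:
        """(source index per canonical axis, sign per canonical axis)."""
        ml_i, ml_s = self._parse(self.ml_axis)
        ap_i, ap_s = self._parse(self.ap_axis)
        vt_i, vt_s = self._parse(self.vert_axis)
        if not self.anterior_positive:
            ap_s = -ap_s
        return np.array([ml_i, ap_i, vt_i]), np.array([ml_s, ap_s, vt_s])

    @classmethod
    def from_dict(cls, d: dict) -> "AxisConfig":
        return cls(
            ml_axis=d.get("ml_axis", "x"),
            ap_axis=d.get("ap_axis", "y"),
            vert_axis=d.get("vert_axis", "z"),
            anterior_positive=bool(d.get("anterior_positive", True)),
        )


IDENTITY_AXES = AxisConfig()


@dataclass
class SkeletonSequence:
    """Timestamped 20-joint 3-D position series in the canonical frame.

    positions has shape (n_frames, 20, 3) in millimetres; ``valid`` flags
    usable samples, ``imputed`` flags samples filled by gap imputation.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    valid: np.ndarray
    sample_rate_hz: float = 15.0
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.timestamps.shape[0]
        if self.positions.shape != (n, N_JOINTS, 3):
            raise ValueError(
                f"positions must have shape ({n}, {N_JOINTS}, 3), got {self.positions.shape}"
            )
        if self.valid.shape != (n, N_JOINTS):
            raise ValueError(f"valid must have shape ({n}, {N_JOINTS}), got {self.valid.shape}")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise SkeletonDataError(f"timestamps not strictly increasing at frame {bad}")
        if self.imputed is None:
            self.imputed = np.zeros((n, N_JOINTS), dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise SkeletonDataError("non-finite position marked valid")

    @property
    def frame_count(self) -> int:
        return int(self.timestamps.shape[0])

    def joint(self, name: str) -> np.ndarray:
        """(n_frames, 3) positions of one joint."""
        return self.positions[:, joint_index(name), :]

    def joint_valid(self, name: str) -> np.ndarray:
        return self.valid[:, joint_index(name)]

    def copy(self) -> "SkeletonSequence":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            positions=self.positions.copy(),
            valid=self.valid.copy(),
            imputed=self.imputed.copy(),
        )


def map_axes(seq: SkeletonSequence, axis_config: AxisConfig) -> SkeletonSequence:
    """Re-express a sequence recorded in device axes in the canonical frame.

    Pure permutation + sign flips, hence an isometry: inter-joint distances
    are preserved for any configuration.
    """
    perm, sign = axis_config.permutation()
    pos = seq.positions[:, :, perm] * sign
    return replace(seq, positions=pos, valid=seq.valid.copy(), imputed=seq.imputed.copy())


def _columns() -> list[str]:
    cols = ["t"]
    for j in CANONICAL_JOINTS:
        cols += [f"{j}_x", f"{j}_y", f"{j}_z"]
    return cols


def read_skeleton(
    path,
    format: str = "csv",
    axis_config: AxisConfig = IDENTITY_AXES,
    joint_map: dict[str, str] | None = None,
    sample_rate_hz: float = 15.0,
) -> SkeletonSequence:
    """Read a joint time series and return it in the canonical frame.

    ``joint_map`` translates file joint names to canonical names (device
    exports often use e.g. ``SPINE_CHEST``); extra joints in the file are
    ignored.  Unparseable or absent samples are marked invalid, never
    zero-filled.
    """
    if format == "csv":
        seq = _read_csv(path, joint_map, sample_rate_hz)
    elif format == "json":
        seq = _read_json(path, joint_map, sample_rate_hz)
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
    return map_axes(seq, axis_config)


def _canonicalize(name: str, joint_map: dict[str, str] | None) -> str | None:
    if joint_map and name in joint_map:
        name = joint_map[name]
    return name if name in JOINT_INDEX else None


def _read_csv(path, joint_map, sample_rate_hz) -> SkeletonSequence:
    try:
        df = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise SkeletonFormatError(f"cannot parse {path} as skeleton CSV: {exc}") from exc
    if "t" not in df.columns:
        raise SkeletonFormatError("missing required column 't'")
    # Map file columns like <joint>_x onto canonical joints.
    col_for: dict[tuple[str, str], str] = {}
    for col in df.columns:
        for ax in ("x", "y", "z"):
            if col.endswith(f"_{ax}"):
                canon = _canonicalize(col[: -2], joint_map)
                if canon is not None:
                    col_for[(canon, ax)] = col
    for j in CANONICAL_JOINTS:
        for ax in ("x", "y", "z"):
            if (j, ax) not in col_for:
                raise SkeletonFormatError(f"missing required column '{j}_{ax}'")
    n = len(df)
    t = df["t"].to_numpy(dtype=float)
    if n > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SkeletonDataError(f"timestamps not strictly increasing at frame {bad}")
    pos = np.zeros((n, N_JOINTS, 3))
    valid = np.zeros((n, N_JOINTS), dtype=bool)
    for j, ji in JOINT_INDEX.items():
        cols = np.column_stack([df[col_for[(j, ax)]].to_numpy(dtype=float) for ax in ("x", "y", "z")])
        ok = np.all(np.isfinite(cols), axis=1)
        pos[:, ji, :] = np.where(ok[:, None], cols, 0.0)
        valid[:, ji] = ok
    return SkeletonSequence(t, pos, valid, sample_rate_hz=sample_rate_hz)


def _read_json(path, joint_map, sample_rate_hz) -> SkeletonSequence:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SkeletonFormatError(f"cannot parse {path} as skeleton JSON: {exc}") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise SkeletonFormatError("skeleton JSON must be an object with a 'frames' array")
    frames = doc["frames"]
    fs = float(doc.get("sample_rate_hz", sample_rate_hz))
    n = len(frames)
    t = np.zeros(n)
    pos = np.zeros((n, N_JOINTS, 3))
    valid = np.zeros((n, N_JOINTS), dtype=bool)
    for i, fr in enumerate(frames):
        if "t" not in fr:
            raise SkeletonFormatError(f"frame {i} missing required field 't'")
        t[i] = float(fr["t"])
        joints = fr.get("joints", {})
        for name, xyz in joints.items():
            canon = _canonicalize(name, joint_map)
            if canon is None or xyz is None:
                continue
            arr = np.asarray(xyz, dtype=float)
            if arr.shape == (3,) and np.all(np.isfinite(arr)):
                ji = JOINT_INDEX[canon]
                pos[i, ji, :] = arr
                valid[i, ji] = True
    if n > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SkeletonDataError(f"timestamps not strictly increasing at frame {bad}")
    return SkeletonSequence(t, pos, valid, sample_rate_hz=fs)


def write_skeleton(seq: SkeletonSequence, path, format: str = "csv") -> None:
    """Write a sequence; round-trips bit-exactly through :func:`read_skeleton`.

    Floats are written with Python's shortest round-trip repr, so
    ``read(write(seq))`` reproduces timestamps and valid positions exactly.
    """
    if format == "csv":
        _write_csv(seq, path)
    elif format == "json":
        _write_json(seq, path)
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def _write_csv(seq: SkeletonSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(_columns()) + "\n")
        for i in range(seq.frame_count):
            cells = [repr(float(seq.timestamps[i]))]
            for ji in range(N_JOINTS):
                if seq.valid[i, ji]:
                    cells += [repr(float(seq.positions[i, ji, k])) for k in range(3)]
                else:
                    cells += ["", "", ""]
            fh.write(",".join(cells) + "\n")


def _write_json(seq: SkeletonSequence, path) -> None:
    frames = []
    for i in range(seq.frame_count):
        joints: dict[str, list[float] | None] = {}
        for j, ji in JOINT_INDEX.items():
            joints[j] = (
                [float(seq.positions[i, ji, k]) for k in range(3)] if seq.valid[i, ji] else None
            )
        frames.append({"t": float(seq.timestamps[i]), "joints": joints})
    with open(path, "w") as fh:
        json.dump({"sample_rate_hz": seq.sample_rate_hz, "frames": frames}, fh)
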