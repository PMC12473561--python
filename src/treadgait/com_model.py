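"""Segmental whole-body centre-of-mass synthesis.

The body is treated as a rigid system of segments, each spanning a proximal
and a distal tracked joint.  A segment's CoM lies a fraction ``l`` of the way
from its proximal to its distal end,

    P_i = P_u - l_i * (P_u - P_l),

and the whole-body CoM is the mass-fraction-weighted sum over segments,

    CoM_body = sum_i r_i * P_i,      sum_i r_i = 1.

The default table (14 segments over the 20 tracked joints, Winter-lineage
values, head+neck merged) ships as a YAML data file and is fully
user-replaceable; see ``data/anthropometric_14.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .joints import JOINT_INDEX
from .skeleton_io import SkeletonSequence


@dataclass(frozen=True)
class SegmentDefinition:
    name: str
    proximal: str  # upper-end joint, P_u
    distal: str  # lower-end joint, P_l
    l: float  # CoM position parameter from the proximal end, in [0, 1]
    r: float  # mass fraction, in (0, 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.l <= 1.0:
            raise ValueError(f"segment {self.name}: position parameter l={self.l} outside [0, 1]")
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"segment {self.name}: mass ratio r={self.r} outside (0, 1)")
        for j in (self.proximal, self.distal):
            if j not in JOINT_INDEX:
                raise ValueError(f"segment {self.name} references unknown joint {j!r}")


@dataclass(frozen=True)
class AnthropometricTable:
    segments: tuple[SegmentDefinition, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        total = sum(s.r for s in self.segments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions must sum to 1, got {total!r}")

    @property
    def referenced_joints(self) -> set[str]:
        out: set[str] = set()
        for s in self.segments:
            out.update((s.proximal, s.distal))
        return out

    def normalized(self) -> "AnthropometricTable":
        """Copy with mass fractions rescaled to sum exactly to 1."""
        total = sum(s.r for s in self.segments)
        return replace(
            self, segments=tuple(replace(s, r=s.r / total) for s in self.segments)
        )

    @classmethod
    def from_dict(cls, doc: dict) -> "AnthropometricTable":
        segs = tuple(
            SegmentDefinition(
                name=d["name"],
                proximal=d["proximal"],
                distal=d["distal"],
                l=float(d["l"]),
                r=float(d["r"]),
            )
            for d in doc["segments"]
        )
        return cls(segments=segs, name=doc.get("name", "custom"))

    @classmethod
    def from_yaml(cls, path) -> "AnthropometricTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_DEFAULT: AnthropometricTable | None = None


def default_table() -> AnthropometricTable:
    """The bundled 14-segment table (validated once, then cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("treadgait").joinpath("data/anthropometric_14.yaml").read_text()
        _DEFAULT = AnthropometricTable.from_dict(yaml.safe_load(text))
    return _DEFAULT


def segment_com(p_upper, p_lower, l: float) -> np.ndarray:
    """CoM of one segment: the point a fraction ``l`` from P_u towards P_l."""
    if not 0.0 <= l <= 1.0:
        raise ValueError(f"position parameter l={l} outside [0, 1]")
    p_upper = np.asarray(p_upper, dtype=float)
    p_lower = np.asarray(p_lower, dtype=float)
    return p_upper - l * (p_upper - p_lower)


def body_com(frame_positions: np.ndarray, table: AnthropometricTable | None = None) -> np.ndarray:
    """Whole-body CoM of a single frame: sum_i r_i * P_i over segment CoMs.

    ``frame_positions`` is the (20, 3) canonical joint array; all joints the
    table references must be valid (use :func:`com_trajectory` for validity
    propagation on a sequence).
    """
    table = table or default_table()
    out = np.zeros(3)
    for s in table.segments:
        pu = frame_positions[JOINT_INDEX[s.proximal]]
        pl = frame_positions[JOINT_INDEX[s.distal]]
        out += s.r * segment_com(pu, pl, s.l)
    return out


@dataclass
class ComTrajectory:
    """Per-frame whole-body CoM (mm, canonical frame) with validity flags."""

    timestamps: np.ndarray
    position: np.ndarray  # (n, 3)
    valid: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.position.shape != (self.timestamps.shape[0], 3):
            raise ValueError("position must have shape (n_frames, 3)")

    @property
    def frame_count(self) -> int:
        return int(self.timestamps.shape[0])


def com_trajectory(seq: SkeletonSequence, table: AnthropometricTable | None = None) -> ComTrajectory:
    """Per-frame whole-body CoM with validity propagation.

    A frame is valid iff every joint the table references is valid there; no
    exception is raised for invalid frames — downstream stride exclusion
    handles them.  Vectorised over frames.
    """
    table = table or default_table()
    joints = sorted(table.referenced_joints)
    missing = [j for j in joints if j not in JOINT_INDEX]
    if missing:
        raise ValueError(f"table references joints absent from the sequence: {missing}")
    idx = np.array([JOINT_INDEX[j] for j in joints])
    valid = np.all(seq.valid[:, idx], axis=1)

    # CoM is linear in joint positions: precompute one weight per joint.
    weights = np.zeros(seq.positions.shape[1])
    for s in table.segments:
        weights[JOINT_INDEX[s.proximal]] += s.r * (1.0 - s.l)
        weights[JOINT_INDEX[s.distal]] += s.r * s.l
    pos = np.einsum("j,njk->nk", weights, seq.positions)
    pos[~valid] = np.nan
    return ComTrajectory(seq.timestamps.copy(), pos, valid)
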