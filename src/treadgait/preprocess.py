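"""Missing-data policy and data-quality accounting.

Depth-camera trackers intermittently lose joints (the feet especially).  The
policy implemented here: an isolated single-frame gap in one joint's track is
filled by linear interpolation in time; any longer gap is left invalid and the
strides that span it are excluded downstream.  A :class:`QualityReport`
summarises frame loss, stride loss, per-joint loss, and the gap-length
distribution so the participant-level exclusion rule (stride loss > 50 %) can
be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .joints import CANONICAL_JOINTS, JOINT_INDEX
from .skeleton_io import SkeletonSequence


@dataclass
class QualityReport:
    frame_loss_pct: float
    stride_loss_pct: float | None
    per_joint_loss: dict[str, float]
    gap_histogram: dict[int, int]
    n_frames: int = 0
    n_strides: int = 0
    n_strides_excluded: int = 0
    required_joints: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "frame_loss_pct": self.frame_loss_pct,
            "stride_loss_pct": self.stride_loss_pct,
            "per_joint_loss": self.per_joint_loss,
            "gap_histogram": {str(k): v for k, v in sorted(self.gap_histogram.items())},
            "n_frames": self.n_frames,
            "n_strides": self.n_strides,
            "n_strides_excluded": self.n_strides_excluded,
            "required_joints": list(self.required_joints),
        }


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of False as (start, length)."""
    runs = []
    n = valid.shape[0]
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def impute_single_frame_gaps(seq: SkeletonSequence) -> SkeletonSequence:
    """Fill isolated one-frame gaps by linear interpolation in time.

    Only maximal invalid runs of length exactly 1 with a valid neighbour on
    both sides are filled (time-weighted, so a jittery clock is handled
    correctly); longer runs and boundary gaps are untouched.  Filled samples
    are flagged in ``imputed``.  Idempotent, and never alters an originally
    valid sample.
    """
    out = seq.copy()
    t = out.timestamps
    n = out.frame_count
    for ji in range(len(CANONICAL_JOINTS)):
        v = out.valid[:, ji]
        for start, length in _invalid_runs(v):
            if length != 1:
                continue
            i = start
            if i == 0 or i == n - 1:
                continue  # boundary gap: no neighbour on one side
            w = (t[i] - t[i - 1]) / (t[i + 1] - t[i - 1])
            out.positions[i, ji, :] = (1.0 - w) * out.positions[i - 1, ji, :] + w * out.positions[
                i + 1, ji, :
            ]
            out.valid[i, ji] = True
            out.imputed[i, ji] = True
    return out


def quality_report(
    seq: SkeletonSequence,
    strides=None,
    required_joints=None,
) -> QualityReport:
    """Frame-, joint- and stride-level loss accounting after imputation.

    A frame counts as lost iff any *required* joint is invalid in it.  A
    stride counts as lost iff its ``excluded`` flag is set.  With no candidate
    strides, stride loss is undefined and reported as None (not 0).  The gap
    histogram reconstructs pre-imputation gap lengths: imputed samples were
    length-1 gaps.
    """
    if required_joints is None:
        required_joints = CANONICAL_JOINTS
    required_joints = tuple(required_joints)
    idx = [JOINT_INDEX[j] for j in required_joints]
    n = seq.frame_count
    lost = ~np.all(seq.valid[:, idx], axis=1) if n else np.zeros(0, dtype=bool)
    frame_loss_pct = 100.0 * lost.sum() / n if n else 0.0

    per_joint = {
        j: (100.0 * (~seq.valid[:, JOINT_INDEX[j]]).sum() / n if n else 0.0)
        for j in CANONICAL_JOINTS
    }

    hist: dict[int, int] = {}
    for ji in range(len(CANONICAL_JOINTS)):
        raw_invalid = ~seq.valid[:, ji] | seq.imputed[:, ji]
        for _, length in _invalid_runs(~raw_invalid):
            hist[length] = hist.get(length, 0) + 1

    strides = list(strides) if strides is not None else []
    n_str = len(strides)
    n_exc = sum(1 for s in strides if getattr(s, "excluded", False))
    stride_loss_pct = (100.0 * n_exc / n_str) if n_str else None

    return QualityReport(
        frame_loss_pct=float(frame_loss_pct),
        stride_loss_pct=stride_loss_pct,
        per_joint_loss=per_joint,
        gap_histogram=hist,
        n_frames=n,
        n_strides=n_str,
        n_strides_excluded=n_exc,
        required_joints=required_joints,
    )


def exclude_participant_rule(report: QualityReport, threshold_pct: float = 50.0) -> bool:
    """True iff the recording should be dropped: stride loss strictly > threshold."""
    if report.stride_loss_pct is None:
        return False
    return report.stride_loss_pct > threshold_pct
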