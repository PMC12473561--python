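"""Canonical joint set for the 20-joint body-tracking skeleton.

The depth-camera body tracker reports more landmarks than the centre-of-mass
model needs; the pipeline works on exactly these 20, which are the joints the
14-segment anthropometric model references.
"""

from __future__ import annotations

CANONICAL_JOINTS: tuple[str, ...] = (
    "head",
    "neck",
    "spine_chest",
    "pelvis",
    "shoulder_left",
    "shoulder_right",
    "elbow_left",
    "elbow_right",
    "wrist_left",
    "wrist_right",
    "hand_tip_left",
    "hand_tip_right",
    "hip_left",
    "hip_right",
    "knee_left",
    "knee_right",
    "ankle_left",
    "ankle_right",
    "foot_left",
    "foot_right",
)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(CANONICAL_JOINTS)}

N_JOINTS = len(CANONICAL_JOINTS)


def joint_index(name: str) -> int:
    """Index of a canonical joint, with a helpful error for unknown names."""
    try:
        return JOINT_INDEX[name]
    except KeyError:
        raise KeyError(
            f"unknown joint {name!r}; canonical joints are {', '.join(CANONICAL_JOINTS)}"
        ) from None
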