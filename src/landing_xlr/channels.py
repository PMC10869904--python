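"""Channel identities for lower-limb landing waveforms.

A *channel* is one (joint, plane, quantity) combination: three joints x
three anatomical planes x {angle, moment} = 18 channels. The canonical
ordering is joint-major, then plane, then quantity, and is relied upon by
the task builder and the relevance aggregation, so it must never change.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Joint(str, Enum):
    ANKLE = "ankle"
    KNEE = "knee"
    HIP = "hip"


class Plane(str, Enum):
    SAGITTAL = "sagittal"
    FRONTAL = "frontal"
    TRANSVERSAL = "transversal"


class Quantity(str, Enum):
    ANGLE = "angle"  # kinematics
    MOMENT = "moment"  # kinetics


@dataclass(frozen=True)
class ChannelId:
    """Identity of one waveform channel."""

    joint: Joint
    plane: Plane
    quantity: Quantity

    @property
    def label(self) -> str:
        return f"{self.joint.value}_{self.plane.value}_{self.quantity.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


#: Canonical channel order: joint-major, then plane, then quantity.
CHANNELS: tuple[ChannelId, ...] = tuple(
    ChannelId(joint, plane, quantity)
    for joint in Joint
    for plane in Plane
    for quantity in Quantity
)

CHANNEL_INDEX: dict[ChannelId, int] = {c: i for i, c in enumerate(CHANNELS)}
N_CHANNELS: int = len(CHANNELS)


def channel_from_label(label: str) -> ChannelId:
    """Parse ``joint_plane_quantity`` back into a :class:`ChannelId`."""
    parts = label.split("_")
    if len(parts) != 3:
        raise ValueError(f"malformed channel label: {label!r}")
    try:
        return ChannelId(Joint(parts[0]), Plane(parts[1]), Quantity(parts[2]))
    except ValueError as exc:
        raise ValueError(f"unknown channel label: {label!r}") from exc
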