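"""Muscle selector: route signed control actions to agonist/antagonist channels.

A positive control action stimulates the agonist (increases the joint angle);
a negative one stimulates the antagonist with the same magnitude.  The two
muscles of a pair are never commanded simultaneously, so co-contraction cannot
occur by construction.

Default channel map (configurable): sagittal pair = tibialis anterior
(dorsiflexion, agonist) / gastrocnemius (plantar flexion); frontal pair =
flexor hallucis longus (inversion, agonist) / peroneus longus & brevis
(eversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pid import ControlAction

__all__ = ["ChannelPair", "ChannelCommand", "route_action", "default_pairs"]

DOF_LABELS = ("sagittal", "frontal")


@dataclass(frozen=True)
class ChannelPair:
    """Agonist/antagonist channel ids for one degree of freedom."""

    agonist_channel: int
    antagonist_channel: int
    dof: str

    def __post_init__(self) -> None:
        if self.agonist_channel == self.antagonist_channel:
            raise ValueError("agonist and antagonist channels must be distinct")
        if self.dof not in DOF_LABELS:
            raise ValueError(f"dof must be one of {DOF_LABELS}, got {self.dof!r}")

    @property
    def channels(self) -> tuple[int, int]:
        return (self.agonist_channel, self.antagonist_channel)


@dataclass(frozen=True)
class ChannelCommand:
    """Non-negative duty percent per channel; absent channels are 0."""

    duties: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, duty in self.duties.items():
            if duty < 0:
                raise ValueError(f"channel {ch} duty must be >= 0, got {duty}")

    def duty(self, channel: int) -> float:
        return self.duties.get(channel, 0.0)

    def merged(self, other: "ChannelCommand") -> "ChannelCommand":
        overlap = set(self.duties) & set(other.duties)
        if overlap:
            raise ValueError(f"channels commanded twice: {sorted(overlap)}")
        return ChannelCommand({**self.duties, **other.duties})


def route_action(action: ControlAction, pair: ChannelPair) -> ChannelCommand:
    """u > 0 -> agonist gets |u|; u < 0 -> antagonist gets |u|; u = 0 -> both 0."""
    u = action.u
    if u > 0:
        duties = {pair.agonist_channel: u, pair.antagonist_channel: 0.0}
    elif u < 0:
        duties = {pair.agonist_channel: 0.0, pair.antagonist_channel: -u}
    else:
        duties = {pair.agonist_channel: 0.0, pair.antagonist_channel: 0.0}
    return ChannelCommand(duties)


def default_pairs() -> dict[str, ChannelPair]:
    """Default channel assignment for the two ankle degrees of freedom."""
    return {
        "sagittal": ChannelPair(agonist_channel=0, antagonist_channel=1, dof="sagittal"),
        "frontal": ChannelPair(agonist_channel=2, antagonist_channel=3, dof="frontal"),
    }
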