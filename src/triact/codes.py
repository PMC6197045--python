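"""Activity class codes and the standard class-merging map.

Ten activity classes are recognised, in a fixed canonical order used for
class indices, confusion-matrix layout and argmax tie-breaking:

    WS  slow walking          WF  fast walking
    RS  slow running          RF  fast running
    SU  walking up stairs     SD  walking down stairs
    JR  jumping rope          ST  standing up
    SI  sitting down          NA  remaining still (no activity)

Mutually confusable pairs merge into seven groups: slow/fast walking into
``WX``, slow/fast running into ``RX``, and the two stair classes into
``SX``; the remaining four classes map to themselves.
"""

from __future__ import annotations

import enum


class ActivityCode(enum.Enum):
    """One of the ten activity classes, in canonical order."""

    WS = "WS"
    WF = "WF"
    RS = "RS"
    RF = "RF"
    SU = "SU"
    SD = "SD"
    JR = "JR"
    ST = "ST"
    SI = "SI"
    NA = "NA"

    @property
    def merged_group(self) -> "MergedGroup":
        return MERGED_MAP[self]

    @property
    def index(self) -> int:
        """Position in the canonical order (WS=0 ... NA=9)."""
        return CANONICAL_CODES.index(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class MergedGroup(enum.Enum):
    """One of the seven merged activity groups, in canonical order."""

    WX = "WX"
    RX = "RX"
    SX = "SX"
    JR = "JR"
    ST = "ST"
    SI = "SI"
    NA = "NA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CANONICAL_CODES: tuple[ActivityCode, ...] = tuple(ActivityCode)

CANONICAL_MERGED: tuple[MergedGroup, ...] = tuple(MergedGroup)

#: Total, surjective map from the ten classes onto the seven merged groups.
MERGED_MAP: dict[ActivityCode, MergedGroup] = {
    ActivityCode.WS: MergedGroup.WX,
    ActivityCode.WF: MergedGroup.WX,
    ActivityCode.RS: MergedGroup.RX,
    ActivityCode.RF: MergedGroup.RX,
    ActivityCode.SU: MergedGroup.SX,
    ActivityCode.SD: MergedGroup.SX,
    ActivityCode.JR: MergedGroup.JR,
    ActivityCode.ST: MergedGroup.ST,
    ActivityCode.SI: MergedGroup.SI,
    ActivityCode.NA: MergedGroup.NA,
}

#: The same map keyed and valued by plain label strings, for use with
#: :class:`triact.evaluation.ConfusionMatrix`.
MERGED_LABEL_MAP: dict[str, str] = {
    code.value: group.value for code, group in MERGED_MAP.items()
}
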