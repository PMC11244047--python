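"""The seven Bafa Wubu motion sets.

The Bafa Wubu routine combines the eight methods and five steps of tai chi
into seven distinct motion sets: two advancing, two retreating, two lateral
and one static stance.  The class order below is fixed and used everywhere a
class axis appears (confusion matrices, reports, model outputs).
"""

from __future__ import annotations

import enum


class MovementClass(str, enum.Enum):
    """One of the seven Bafa Wubu motion sets.

    The enum value is the conventional short code; ``long_name`` gives the
    descriptive English name.
    """

    WOF = "WOF"
    LF = "LF"
    RBB = "RBB"
    PB = "PB"
    PPS = "PPS"
    ELS = "ELS"
    SKR = "SKR"

    @property
    def long_name(self) -> str:
        return _LONG_NAMES[self]


_LONG_NAMES = {
    MovementClass.WOF: "progressive ward-off",
    MovementClass.LF: "progressive press",
    MovementClass.RBB: "retreating roll-back",
    MovementClass.PB: "retreating pluck",
    MovementClass.PPS: "lateral push and pull",
    MovementClass.ELS: "lateral elbow and lean",
    MovementClass.SKR: "static knee lift",
}

#: Canonical class order for matrices and reports.
CLASS_ORDER: tuple[MovementClass, ...] = (
    MovementClass.WOF,
    MovementClass.LF,
    MovementClass.RBB,
    MovementClass.PB,
    MovementClass.PPS,
    MovementClass.ELS,
    MovementClass.SKR,
)

#: Label used for samples inside cross-fades between scripted movements.
TRANSITION_LABEL = "transition"


def as_code(label: "MovementClass | str") -> str:
    """Normalize a movement label (enum member or string code) to its code."""
    if isinstance(label, MovementClass):
        return label.value
    code = str(label)
    if code != TRANSITION_LABEL and code not in MovementClass.__members__:
        raise ValueError(f"unknown movement label: {label!r}")
    return code
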