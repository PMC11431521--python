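"""The 17-disaccharide free-GAG panel.

Free glycosaminoglycans in plasma are depolymerized into disaccharides and
quantified per sulfation pattern: eight chondroitin sulfate (CS) forms, eight
heparan sulfate (HS) forms, and one hyaluronic acid (HA) disaccharide. Each
disaccharide is identified by its GAG class and a sulfation code (0S =
unsulfated, 4S/6S/2S/NS = mono-sulfated positions, composite codes such as
NS6S for di-sulfated, TriS for tri-sulfated).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class GagClass(str, Enum):
    """GAG class of a disaccharide."""

    CS = "CS"
    HS = "HS"
    HA = "HA"


#: Number of sulfo groups carried by each sulfation code.
SULFO_COUNTS: dict[str, int] = {
    "0S": 0,
    "2S": 1,
    "6S": 1,
    "4S": 1,
    "NS": 1,
    "2S6S": 2,
    "2S4S": 2,
    "4S6S": 2,
    "NS6S": 2,
    "NS2S": 2,
    "TriS": 3,
}

_CS_CODES = ("0S", "2S", "6S", "4S", "2S6S", "2S4S", "4S6S", "TriS")
_HS_CODES = ("0S", "2S", "6S", "NS", "NS6S", "NS2S", "2S6S", "TriS")
_HA_CODES = ("0S",)


@dataclass(frozen=True)
class Disaccharide:
    """One of the 17 valid GAG disaccharide identities."""

    gag_class: GagClass
    sulfation_code: str

    def __post_init__(self) -> None:
        valid = _VALID_CODES.get(self.gag_class)
        if valid is None or self.sulfation_code not in valid:
            raise ValueError(
                f"unknown disaccharide identity: {self.sulfation_code} "
                f"{getattr(self.gag_class, 'value', self.gag_class)}"
            )

    @property
    def canonical_name(self) -> str:
        """Field-standard name, e.g. ``"0S CS"`` or ``"TriS HS"``."""
        return f"{self.sulfation_code} {self.gag_class.value}"

    @property
    def column_name(self) -> str:
        """CSV column identifier, e.g. ``"CS_0S"``."""
        return f"{self.gag_class.value}_{self.sulfation_code}"

    @property
    def sulfo_count(self) -> int:
        return SULFO_COUNTS[self.sulfation_code]


_VALID_CODES: dict[GagClass, tuple[str, ...]] = {
    GagClass.CS: _CS_CODES,
    GagClass.HS: _HS_CODES,
    GagClass.HA: _HA_CODES,
}

#: The full panel in canonical order: 8 CS, 8 HS, 1 HA.
PANEL: tuple[Disaccharide, ...] = tuple(
    Disaccharide(cls, code)
    for cls, codes in ((GagClass.CS, _CS_CODES), (GagClass.HS, _HS_CODES), (GagClass.HA, _HA_CODES))
    for code in codes
)

PANEL_NAMES: tuple[str, ...] = tuple(d.canonical_name for d in PANEL)
PANEL_COLUMNS: tuple[str, ...] = tuple(d.column_name for d in PANEL)

_BY_NAME = {d.canonical_name: d for d in PANEL}
_BY_COLUMN = {d.column_name: d for d in PANEL}


def disaccharide(name: str) -> Disaccharide:
    """Resolve a canonical name ("0S CS") or column name ("CS_0S").

    Raises ``ValueError`` naming the offending identifier if it is not one of
    the 17 panel members.
    """
    d = _BY_NAME.get(name) or _BY_COLUMN.get(name)
    if d is None:
        raise ValueError(f"unknown disaccharide identity: {name!r}")
    return d


def sulfo_count(d: Disaccharide | str) -> int:
    """Number of sulfo groups of a panel disaccharide (0 for 0S ... 3 for TriS)."""
    if isinstance(d, str):
        d = disaccharide(d)
    return d.sulfo_count


def class_members(gag_class: GagClass | str) -> tuple[Disaccharide, ...]:
    """Panel disaccharides of one GAG class, in canonical order."""
    gag_class = GagClass(gag_class)
    return tuple(d for d in PANEL if d.gag_class == gag_class)
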