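"""MDS-UPDRS item catalogue.

Items are identified by their canonical labels ("1.7", "2.11", "3.3a", ...).
Part IA (rater-administered non-motor, 6 items) and Part IB (patient-reported
non-motor, 7 items) together form Part I; Part II (motor experiences of daily
living) has 13 patient-reported items; Part III (motor examination) has 33
distinct scores once laterality / limb sub-items are expanded.  Every item is
scored on the same ordinal 0-4 response scale.

The emergent-symptom method only ever scores Parts IB and II (the
patient-reported instrument); Parts IA and III exist here so summed scores
(Part I, Part III, I+II+III) can be formed for correlation analyses.
"""

from __future__ import annotations

from typing import NamedTuple

PART_IA: tuple[str, ...] = tuple(f"1.{i}" for i in range(1, 7))
PART_IB: tuple[str, ...] = tuple(f"1.{i}" for i in range(7, 14))
PART_II: tuple[str, ...] = tuple(f"2.{i}" for i in range(1, 14))

# Part III with laterality/limb sub-items expanded to distinct codes:
# 3.3 rigidity (neck + 4 limbs), 3.4-3.8 limb bradykinesia and tremor-adjacent
# tasks (right/left), 3.15-3.16 tremor (right/left), 3.17 rest-tremor
# amplitude (4 limbs + lip/jaw).  33 scores total.
PART_III: tuple[str, ...] = (
    "3.1",
    "3.2",
    "3.3a", "3.3b", "3.3c", "3.3d", "3.3e",
    "3.4a", "3.4b",
    "3.5a", "3.5b",
    "3.6a", "3.6b",
    "3.7a", "3.7b",
    "3.8a", "3.8b",
    "3.9",
    "3.10",
    "3.11",
    "3.12",
    "3.13",
    "3.14",
    "3.15a", "3.15b",
    "3.16a", "3.16b",
    "3.17a", "3.17b", "3.17c", "3.17d", "3.17e",
    "3.18",
)

PART_I: tuple[str, ...] = PART_IA + PART_IB
IB_PLUS_II: tuple[str, ...] = PART_IB + PART_II
ALL_ITEMS: tuple[str, ...] = PART_IA + PART_IB + PART_II + PART_III

assert len(PART_IA) == 6 and len(PART_IB) == 7
assert len(PART_II) == 13 and len(PART_III) == 33
assert len(IB_PLUS_II) == 20

#: ES-eligible item sets, keyed the way :class:`esmeasure.scoring.ESConfig`
#: names them.
ITEM_SETS: dict[str, tuple[str, ...]] = {
    "IB": PART_IB,
    "II": PART_II,
    "IB_plus_II": IB_PLUS_II,
}

#: Summed-score blocks used by the correlation analyses.
SCORE_BLOCKS: dict[str, tuple[str, ...]] = {
    "I": PART_I,
    "II": PART_II,
    "III": PART_III,
    "I_II_III": PART_I + PART_II + PART_III,
    "IB_II": IB_PLUS_II,
}


class ItemCode(NamedTuple):
    """An item label together with the scale part it belongs to."""

    part: str  # one of "IA", "IB", "II", "III"
    code: str


_PART_OF: dict[str, str] = {}
for _part, _codes in (("IA", PART_IA), ("IB", PART_IB), ("II", PART_II), ("III", PART_III)):
    for _c in _codes:
        _PART_OF[_c] = _part


def parse_item(code: str) -> ItemCode:
    """Resolve a canonical item label to an :class:`ItemCode`.

    Raises :class:`KeyError` for labels outside the catalogue.
    """
    return ItemCode(_PART_OF[code], code)


def part_of(code: str) -> str:
    """Scale part ("IA", "IB", "II" or "III") of a canonical item label."""
    return _PART_OF[code]
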