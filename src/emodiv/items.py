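"""Canonical modified Differential Emotions Scale (mDES) item set.

The instrument asks how strongly each of 18 discrete emotions is felt in
general, on a 0 ("not at all") to 4 ("extremely") Likert scale. Ten items
are positively valenced and eight negatively valenced. The canonical
ordering below (positive block, then negative block) is used by every
reader, writer and in-memory table in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

POSITIVE_ITEMS: tuple[str, ...] = (
    "amusement",
    "awe",
    "content",
    "joy",
    "gratitude",
    "hope",
    "interest",
    "love",
    "pride",
    "surprise",
)

NEGATIVE_ITEMS: tuple[str, ...] = (
    "anger",
    "shame",
    "fear",
    "disgust",
    "embarrassment",
    "guilt",
    "sadness",
    "contempt",
)

ALL_ITEMS: tuple[str, ...] = POSITIVE_ITEMS + NEGATIVE_ITEMS

#: Number of Likert response options (0..4).
N_LIKERT_LEVELS = 5

_VALENCE = {name: "positive" for name in POSITIVE_ITEMS}
_VALENCE.update({name: "negative" for name in NEGATIVE_ITEMS})


@dataclass(frozen=True)
class EmotionItem:
    """One mDES item: its canonical label and valence class."""

    name: str
    valence: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.name not in _VALENCE:
            raise ValueError(f"unknown mDES item: {self.name!r}")
        if self.valence != _VALENCE[self.name]:
            raise ValueError(
                f"item {self.name!r} has valence {_VALENCE[self.name]!r}, "
                f"not {self.valence!r}"
            )


def item_valence(name: str) -> str:
    """Return ``"positive"`` or ``"negative"`` for a canonical item name."""
    return _VALENCE[canonical_item(name)]


def canonical_item(name: str) -> str:
    """Resolve an item label case-insensitively to its canonical form.

    Raises ``KeyError`` for labels outside the 18-item set.
    """
    key = name.strip().lower()
    if key not in _VALENCE:
        raise KeyError(f"not an mDES emotion item: {name!r}")
    return key


def items_of_valence(valence: str) -> tuple[str, ...]:
    if valence == "positive":
        return POSITIVE_ITEMS
    if valence == "negative":
        return NEGATIVE_ITEMS
    raise ValueError(f"valence must be 'positive' or 'negative', got {valence!r}")
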