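"""The five manual-activity categories.

Activities of daily living are grouped by how the two hands share the work and
whether the fingers move independently of the wrist:

* ``unimanual`` — one hand does essentially all the work.
* ``bimanual_stab_finger`` — one hand stabilizes an object while the active
  hand's fingers move independently (e.g. writing).
* ``bimanual_stab_global`` — stabilizing hand plus whole-hand movement of the
  active hand (e.g. spreading butter).
* ``bimanual_both_finger`` — both hands active with independent finger
  movement (e.g. typing, buttoning).
* ``bimanual_both_global`` — both hands active, moving as whole hands
  (e.g. lifting a pan, wringing a towel).
"""

from __future__ import annotations

from enum import Enum


class Category(str, Enum):
    """Closed enumeration of the five activity categories."""

    UNIMANUAL = "unimanual"
    BIMANUAL_STAB_FINGER = "bimanual_stab_finger"
    BIMANUAL_STAB_GLOBAL = "bimanual_stab_global"
    BIMANUAL_BOTH_FINGER = "bimanual_both_finger"
    BIMANUAL_BOTH_GLOBAL = "bimanual_both_global"

    @property
    def display_label(self) -> str:
        return _DISPLAY[self]

    @property
    def is_bimanual(self) -> bool:
        return self is not Category.UNIMANUAL

    @property
    def is_stabilizing(self) -> bool:
        return self in (Category.BIMANUAL_STAB_FINGER, Category.BIMANUAL_STAB_GLOBAL)

    @property
    def is_finger(self) -> bool:
        """True when the category implies independent finger activity."""
        return self in (Category.BIMANUAL_STAB_FINGER, Category.BIMANUAL_BOTH_FINGER)

    @classmethod
    def parse(cls, value: "str | Category") -> "Category":
        """Parse a canonical short name or a full display label.

        Raises ``ValueError`` naming the offending label for anything else.
        """
        if isinstance(value, Category):
            return value
        text = str(value).strip()
        try:
            return cls(text)
        except ValueError:
            pass
        for cat, label in _DISPLAY.items():
            if text.lower() == label.lower():
                return cat
        raise ValueError(
            f"unknown category {text!r}; expected one of "
            f"{[c.value for c in cls]}"
        )


_DISPLAY = {
    Category.UNIMANUAL: "Unimanual",
    Category.BIMANUAL_STAB_FINGER: (
        "Bimanual with a stabilizing hand and finger activity of the active hand"
    ),
    Category.BIMANUAL_STAB_GLOBAL: (
        "Bimanual with a stabilizing hand and global activity of the active hand"
    ),
    Category.BIMANUAL_BOTH_FINGER: "Bimanual with finger activity of both hands",
    Category.BIMANUAL_BOTH_GLOBAL: "Bimanual with a global activity of both hands",
}

CATEGORIES = tuple(Category)
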