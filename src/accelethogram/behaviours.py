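"""Closed behaviour vocabulary for the ethogram.

Five classes, ordered by descending expected prevalence in a free-swimming
fish; this order also breaks majority-vote ties deterministically in the
classifier.
"""

from __future__ import annotations

BEHAVIOUR_CLASSES: tuple[str, ...] = ("swim", "feed", "escape", "courtship", "chafe")

#: Background locomotion state; everything else is embedded in it.
BACKGROUND = "swim"


def parse_behaviour(value: str) -> str:
    """Parse a behaviour label case-insensitively to its canonical form.

    Raises ``ValueError`` for labels outside the closed vocabulary.
    """
    canonical = str(value).strip().lower()
    if canonical not in BEHAVIOUR_CLASSES:
        raise ValueError(
            f"unknown behaviour {value!r}; expected one of {BEHAVIOUR_CLASSES}"
        )
    return canonical


def behaviour_code(label: str) -> int:
    """Integer code of a canonical label (position in ``BEHAVIOUR_CLASSES``)."""
    return BEHAVIOUR_CLASSES.index(parse_behaviour(label))
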