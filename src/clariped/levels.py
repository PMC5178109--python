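"""Ordered urgency levels shared by every component of the tool."""

from __future__ import annotations

import enum


class UrgencyLevel(enum.IntEnum):
    """Five-level urgency scale, ordered by clinical urgency.

    Comparison operators follow urgency: ``BLUE < GREEN < YELLOW <
    ORANGE < RED``.
    """

    BLUE = 0
    GREEN = 1
    YELLOW = 2
    ORANGE = 3
    RED = 4

    @classmethod
    def from_name(cls, name: str) -> "UrgencyLevel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown urgency level: {name!r}") from None

    def __str__(self) -> str:  # CSV-friendly
        return self.name


#: Levels from least to most urgent.
LEVELS_ASCENDING = tuple(UrgencyLevel)

#: Conventional display order (most urgent first), as used in reports.
LEVELS_DESCENDING = tuple(reversed(LEVELS_ASCENDING))
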