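"""Traffic-light severity grades for drug-drug interactions.

The clinical traffic-light grading uses four ordered categories:
Green (no interaction expected) < Yellow (weak relevance) <
Amber (manageable by monitoring / dose adjustment) < Red (do not
co-administer).  Internally grades are the integers 0..3; files carry
the names.
"""

from __future__ import annotations

import enum


class GradeLabel(enum.IntEnum):
    """Ordered four-level DDI severity code."""

    GREEN = 0
    YELLOW = 1
    AMBER = 2
    RED = 3

    @property
    def display(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_token(cls, token: str | int) -> "GradeLabel":
        """Parse a grade from a case-insensitive name or a 0-3 code.

        Raises ValueError for unknown tokens.
        """
        if isinstance(token, (int,)) and not isinstance(token, bool):
            return cls(token)
        text = str(token).strip()
        if text.isdigit():
            return cls(int(text))
        try:
            return cls[text.upper()]
        except KeyError:
            raise ValueError(f"unknown grade token: {token!r}") from None


#: Grades in severity order; index == integer code.
GRADE_ORDER: tuple[GradeLabel, ...] = (
    GradeLabel.GREEN,
    GradeLabel.YELLOW,
    GradeLabel.AMBER,
    GradeLabel.RED,
)

N_GRADES = len(GRADE_ORDER)
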