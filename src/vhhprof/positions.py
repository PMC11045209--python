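"""Chothia positions for antibody heavy-chain variable domains.

The Chothia scheme numbers heavy-chain variable-domain residues 1-113 and
accommodates loop-length variation with insertion letters appended to a base
number (31A-31G inside HCDR1, 52A-52I inside HCDR2, 100A-100B and beyond in
HCDR3 are the common ones).  Positions are totally ordered:

    (n) < (n, 'A') < (n, 'B') < ... < (n + 1)

so sorting a list of positions is deterministic regardless of input order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

MIN_NUMBER = 1
MAX_NUMBER = 113

_LABEL_RE = re.compile(r"^([0-9]{1,3})([A-Z]?)$")


@total_ordering
@dataclass(frozen=True)
class ChothiaPosition:
    """A Chothia base number (1-113) with an optional insertion letter."""

    number: int
    insertion: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.number, int) or not (MIN_NUMBER <= self.number <= MAX_NUMBER):
            raise ValueError(
                f"Chothia base number must be an integer in "
                f"[{MIN_NUMBER}, {MAX_NUMBER}], got {self.number!r}"
            )
        if self.insertion is not None:
            ins = self.insertion
            if not (isinstance(ins, str) and len(ins) == 1 and "A" <= ins <= "Z"):
                raise ValueError(
                    f"insertion must be a single uppercase letter A-Z, got {ins!r}"
                )

    @property
    def label(self) -> str:
        """Rendered form, e.g. ``100`` or ``100A``."""
        return f"{self.number}{self.insertion or ''}"

    def sort_key(self) -> tuple[int, str]:
        # '' < 'A' < ... < 'Z' gives the base position before its insertions
        return (self.number, self.insertion or "")

    def __lt__(self, other: "ChothiaPosition") -> bool:
        if not isinstance(other, ChothiaPosition):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "ChothiaPosition":
        """Parse a rendered position label such as ``26`` or ``52A``."""
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise ValueError(f"malformed Chothia position label: {label!r}")
        number = int(m.group(1))
        insertion = m.group(2) or None
        return cls(number, insertion)


def compare_positions(a: ChothiaPosition, b: ChothiaPosition) -> int:
    """Three-way comparison of two Chothia positions (-1, 0 or 1)."""
    ka, kb = a.sort_key(), b.sort_key()
    return (ka > kb) - (ka < kb)
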