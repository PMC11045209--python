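"""Framework / HCDR region windows over the Chothia numbering.

The default scheme splits positions 1-113 into seven contiguous windows:

=======  ==========
region   positions
=======  ==========
FW1      1-25
HCDR1    26-32
FW2      33-51
HCDR2    52-56
FW3      57-94
HCDR3    95-102
FW4      103-113
=======  ==========

A position carrying an insertion letter belongs to the window containing its
base number (so 100A is HCDR3, 31F is HCDR1).  Named landmarks are the
canonical intradomain cysteines (22, 92), the salt-bridge pair flanking
HCDR3 (basic 94, acidic 101) and the conserved tryptophan opening FW4 (103).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .positions import MAX_NUMBER, MIN_NUMBER, ChothiaPosition

REGION_ORDER = ("FW1", "HCDR1", "FW2", "HCDR2", "FW3", "HCDR3", "FW4")

DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "FW1": (1, 25),
    "HCDR1": (26, 32),
    "FW2": (33, 51),
    "HCDR2": (52, 56),
    "FW3": (57, 94),
    "HCDR3": (95, 102),
    "FW4": (103, 113),
}

DEFAULT_LANDMARKS: dict[str, int] = {
    "canonical_cys_1": 22,
    "canonical_cys_2": 92,
    "salt_bridge_basic": 94,
    "salt_bridge_acidic": 101,
    "conserved_trp": 103,
}


@dataclass(frozen=True)
class RegionScheme:
    """Window table mapping region names to inclusive base-number intervals."""

    windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    landmarks: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARKS)
    )

    def __post_init__(self) -> None:
        names = list(self.windows)
        if set(names) != set(REGION_ORDER):
            raise ValueError(f"windows must name exactly {REGION_ORDER}")
        # windows must tile 1-113 in region order with no overlap or gap
        expected_start = MIN_NUMBER
        for name in REGION_ORDER:
            lo, hi = self.windows[name]
            if lo != expected_start or hi < lo:
                raise ValueError(
                    f"window {name}={lo}-{hi} does not tile contiguously "
                    f"(expected start {expected_start})"
                )
            expected_start = hi + 1
        if expected_start != MAX_NUMBER + 1:
            raise ValueError(f"windows must end at {MAX_NUMBER}")

    def region_of(self, pos: ChothiaPosition) -> str:
        """Region containing a position (by its base number)."""
        for name in REGION_ORDER:
            lo, hi = self.windows[name]
            if lo <= pos.number <= hi:
                return name
        raise ValueError(f"position {pos} outside 1-{MAX_NUMBER}")  # pragma: no cover

    def window_positions(self, region: str) -> range:
        """Base numbers of a region window."""
        lo, hi = self.windows[region]
        return range(lo, hi + 1)

    def landmark(self, name: str) -> ChothiaPosition:
        return ChothiaPosition(self.landmarks[name])


def default_scheme() -> RegionScheme:
    return RegionScheme()


def segment(seq, scheme: RegionScheme | None = None):
    """Partition a numbered sequence into its region windows.

    Returns a dict mapping every region name to an ordered list of
    ``(ChothiaPosition, residue)`` pairs; empty regions map to empty lists.
    Concatenating the regions in FW1..FW4 order reproduces the input.
    """
    scheme = scheme or default_scheme()
    out: dict[str, list[tuple[ChothiaPosition, str]]] = {r: [] for r in REGION_ORDER}
    for pos, res in seq.items():
        out[scheme.region_of(pos)].append((pos, res))
    return out
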