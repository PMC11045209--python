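"""Containers for Chothia-numbered variable-domain sequences."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .positions import ChothiaPosition

#: the 20 standard residues plus the ambiguity codes B (D/N), Z (E/Q) and X
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("BZX")

DOMAIN_CLASSES = ("VH", "VHH")


@dataclass
class NumberedSequence:
    """One variable-domain sequence keyed by Chothia position.

    Absent (unresolved or deleted) positions are simply missing keys; gap
    characters are never stored.  Residues are kept sorted in Chothia order.
    """

    id: str
    species: str
    domain_class: str
    residues: dict[ChothiaPosition, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(
                f"domain_class must be one of {DOMAIN_CLASSES}, got {self.domain_class!r}"
            )
        for pos, res in self.residues.items():
            if res not in VALID_RESIDUES:
                raise ValueError(f"unknown residue letter {res!r} at position {pos}")
        self.residues = dict(sorted(self.residues.items(), key=lambda kv: kv[0].sort_key()))

    def items(self) -> Iterator[tuple[ChothiaPosition, str]]:
        return iter(self.residues.items())

    def positions(self) -> list[ChothiaPosition]:
        return list(self.residues)

    def residue_at(self, pos: ChothiaPosition) -> str | None:
        """Residue at a position, or None when the position is absent."""
        return self.residues.get(pos)

    def sequence_string(self) -> str:
        return "".join(self.residues.values())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceDataset:
    """A labelled collection of numbered sequences plus free-text provenance."""

    records: list[NumberedSequence] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes[:5]}")

    def __iter__(self) -> Iterator[NumberedSequence]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_class(self, domain_class: str) -> "SequenceDataset":
        return SequenceDataset(
            [r for r in self.records if r.domain_class == domain_class],
            dict(self.provenance),
        )

    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def classes(self) -> list[str]:
        return sorted({r.domain_class for r in self.records})

    def extend(self, records: Iterable[NumberedSequence]) -> None:
        self.records.extend(records)
        self.__post_init__()
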