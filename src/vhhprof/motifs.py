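"""Position-frequency matrices, information content and consensus motifs.

The information content of an alignment column is measured against the
20-letter protein alphabet:

    bits = log2(20) - H(freqs),   H in bits

with no small-sample correction, matching the classic frequency-based logo
computation.  Columns are Chothia positions; per-column frequencies are
computed over the sequences occupying the position (X residues are excluded
from frequencies but still count toward occupancy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .dataset import SequenceDataset
from .positions import ChothiaPosition

MAX_BITS = math.log2(20)


@dataclass
class LogoMatrix:
    """Per-position residue frequencies, occupancy and information content."""

    columns: list[ChothiaPosition]
    freqs: dict[ChothiaPosition, dict[str, float]]
    occupancy: dict[ChothiaPosition, float]
    bits: dict[ChothiaPosition, float]
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format (position, residue, frequency, occupancy, bits,
        weighted_bits) table ready for logo-rendering tools."""
        rows = []
        for pos in self.columns:
            for res, f in sorted(self.freqs[pos].items()):
                rows.append(
                    {
                        "position": pos.label,
                        "residue": res,
                        "frequency": f,
                        "occupancy": self.occupancy[pos],
                        "bits": self.bits[pos],
                        "weighted_bits": self.bits[pos] * self.occupancy[pos],
                    }
                )
        return pd.DataFrame(rows)


def column_bits(freqs: dict[str, float]) -> float:
    """Information content (bits) of one column from residue frequencies."""
    if not freqs:
        raise ValueError("all-zero column: no residue frequencies")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1, got {total!r}")
    entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
    return max(0.0, MAX_BITS - entropy)


def frequency_matrix(
    ds: SequenceDataset, class_filter: str | None = None
) -> LogoMatrix:
    """Position-frequency matrix over a dataset (optionally one class)."""
    records = list(ds) if class_filter is None else [
        r for r in ds if r.domain_class == class_filter
    ]
    if not records:
        raise ValueError(f"no sequences selected (class_filter={class_filter!r})")
    n = len(records)
    counts: dict[ChothiaPosition, dict[str, int]] = {}
    occupied: dict[ChothiaPosition, int] = {}
    for rec in records:
        for pos, res in rec.items():
            occupied[pos] = occupied.get(pos, 0) + 1
            if res == "X":
                continue
            col = counts.setdefault(pos, {})
            col[res] = col.get(res, 0) + 1
    columns = sorted(occupied, key=lambda p: p.sort_key())
    freqs: dict[ChothiaPosition, dict[str, float]] = {}
    bits: dict[ChothiaPosition, float] = {}
    occupancy: dict[ChothiaPosition, float] = {}
    for pos in columns:
        occupancy[pos] = occupied[pos] / n
        col = counts.get(pos, {})
        total = sum(col.values())
        if total:
            freqs[pos] = {res: c / total for res, c in col.items()}
            bits[pos] = column_bits(freqs[pos])
        else:  # position occupied only by X residues
            freqs[pos] = {}
            bits[pos] = 0.0
    return LogoMatrix(columns, freqs, occupancy, bits, n)


def consensus(lm: LogoMatrix) -> dict[ChothiaPosition, tuple[str, bool]]:
    """Per-column consensus residue with a tie flag.

    Ties break alphabetically; the flag marks columns where the maximal
    frequency is shared by more than one residue.
    """
    if not lm.columns:
        raise ValueError("empty logo matrix")
    out: dict[ChothiaPosition, tuple[str, bool]] = {}
    for pos in lm.columns:
        col = lm.freqs[pos]
        if not col:
            continue
        peak = max(col.values())
        winners = sorted(res for res, f in col.items() if f == peak)
        out[pos] = (winners[0], len(winners) > 1)
    return out


def motif_at(lm: LogoMatrix, positions: list[ChothiaPosition]) -> str:
    """Concatenated consensus residues at the requested positions.

    Unoccupied positions contribute the placeholder ``-``.
    """
    cons = consensus(lm)
    return "".join(cons[p][0] if p in cons else "-" for p in positions)
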