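"""HCDR/FW length metrics: per-region lengths, length-frequency
distributions and per-(class, species) summary tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .dataset import NumberedSequence, SequenceDataset
from .regions import REGION_ORDER, RegionScheme, default_scheme


def region_length(
    seq: NumberedSequence, region: str, scheme: RegionScheme | None = None
) -> int:
    """Number of occupied positions (base + insertions) inside a region."""
    scheme = scheme or default_scheme()
    if region not in scheme.windows:
        raise ValueError(f"unknown region {region!r}")
    lo, hi = scheme.windows[region]
    return sum(1 for pos in seq.positions() if lo <= pos.number <= hi)


def _smallest_mode(histogram: dict[int, int]) -> tuple[int, list[int]]:
    """Smallest modal length plus the full list of tied modes."""
    peak = max(histogram.values())
    modes = sorted(length for length, count in histogram.items() if count == peak)
    return modes[0], modes


def length_distribution(
    ds: SequenceDataset, region: str, scheme: RegionScheme | None = None
) -> dict[str, dict[int, float]]:
    """Per-class relative frequency of region lengths (frequencies sum to 1)."""
    scheme = scheme or default_scheme()
    out: dict[str, dict[int, float]] = {}
    for domain_class in ds.classes():
        sub = [r for r in ds if r.domain_class == domain_class]
        if not sub:
            warnings.warn(f"no sequences of class {domain_class}; omitted")
            continue
        counts: dict[int, int] = {}
        for rec in sub:
            n = region_length(rec, region, scheme)
            counts[n] = counts.get(n, 0) + 1
        total = len(sub)
        out[domain_class] = {k: v / total for k, v in sorted(counts.items())}
    return out


@dataclass
class LengthSummary:
    """Per (class, species, region) counts, means, modes and histograms."""

    table: pd.DataFrame
    histograms: dict[tuple[str, str, str], dict[int, int]] = field(default_factory=dict)
    tied_modes: dict[tuple[str, str, str], list[int]] = field(default_factory=dict)


def species_summary(
    ds: SequenceDataset,
    regions: tuple[str, ...] = ("HCDR1", "HCDR2", "HCDR3"),
    scheme: RegionScheme | None = None,
) -> LengthSummary:
    """Length summary table, one row per (class, species, region).

    Sequences with an entirely missing region contribute length 0 and are
    counted; the per-row ``n_missing`` column reports how many.  Means are
    reported to one decimal; mode ties break to the smallest length with all
    tied modes retained in :attr:`LengthSummary.tied_modes`.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    scheme = scheme or default_scheme()
    groups: dict[tuple[str, str], list[NumberedSequence]] = {}
    for rec in ds:
        groups.setdefault((rec.domain_class, rec.species), []).append(rec)

    rows = []
    histograms: dict[tuple[str, str, str], dict[int, int]] = {}
    tied: dict[tuple[str, str, str], list[int]] = {}
    for (domain_class, species), members in sorted(groups.items()):
        for region in regions:
            lengths = [region_length(r, region, scheme) for r in members]
            hist: dict[int, int] = {}
            for n in lengths:
                hist[n] = hist.get(n, 0) + 1
            mode, modes = _smallest_mode(hist)
            key = (domain_class, species, region)
            histograms[key] = dict(sorted(hist.items()))
            tied[key] = modes
            rows.append(
                {
                    "class": domain_class,
                    "species": species,
                    "region": region,
                    "n": len(members),
                    "mean": round(sum(lengths) / len(lengths), 1),
                    "mode": mode,
                    "n_missing": sum(1 for n in lengths if n == 0),
                }
            )
    return LengthSummary(pd.DataFrame(rows), histograms, tied)


def distribution_frame(ds: SequenceDataset, scheme: RegionScheme | None = None) -> pd.DataFrame:
    """Tidy (class, region, length, frequency) table over all regions."""
    rows = []
    for region in REGION_ORDER:
        for domain_class, dist in length_distribution(ds, region, scheme).items():
            for length, freq in dist.items():
                rows.append(
                    {"class": domain_class, "region": region,
                     "length": length, "frequency": freq}
                )
    return pd.DataFrame(rows)
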