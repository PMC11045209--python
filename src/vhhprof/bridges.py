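"""Sequence-level disulfide and salt-bridge rule classification.

Disulfide rule: the canonical intradomain bond is the cysteine pair at
Chothia positions 22 and 92.  Any further cysteines are "extra"; they are
paired greedily in ascending position order (1st with 2nd, 3rd with 4th, ...)
and each putative pair is labelled by the region pair it connects
(e.g. ``HCDR1-HCDR3``).  An odd leftover cysteine sets the unpaired flag.

Salt-bridge rule at positions 94 (basic) and 101 (acidic):

* canonical     — R at 94 and D at 101;
* noncanonical  — 94 in {R, K, H} and 101 in {D, E}, excluding the canonical
  pair (histidine counts as basic under this rule);
* none          — everything else, including either position being absent.

Species-level aggregation mirrors the usual survey-table shape: the
salt-bridge triple partitions each species total, whereas "noncanonical"
disulfide counts sequences that *also* carry the canonical bond (a subset of
the canonical column, not a partition cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .dataset import NumberedSequence, SequenceDataset
from .positions import ChothiaPosition
from .regions import REGION_ORDER, RegionScheme, default_scheme

BASIC_94 = frozenset("RKH")
ACIDIC_101 = frozenset("DE")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero to the printed precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DisulfideProfile:
    canonical_present: bool
    extra_cys: list[ChothiaPosition]
    inferred_pairs: list[tuple[ChothiaPosition, ChothiaPosition]]
    pair_categories: list[str]
    unpaired_flag: bool


@dataclass(frozen=True)
class SaltBridgeClass:
    value: str  # canonical | noncanonical | none


def classify_disulfide(
    seq: NumberedSequence, scheme: RegionScheme | None = None
) -> DisulfideProfile:
    """Profile the cysteines of a sequence (canonical + putative extra pairs)."""
    scheme = scheme or default_scheme()
    cys1 = scheme.landmark("canonical_cys_1")
    cys2 = scheme.landmark("canonical_cys_2")
    canonical_present = seq.residue_at(cys1) == "C" and seq.residue_at(cys2) == "C"
    extra = sorted(
        (pos for pos, res in seq.items() if res == "C" and pos not in (cys1, cys2)),
        key=lambda p: p.sort_key(),
    )
    pairs = [(extra[i], extra[i + 1]) for i in range(0, len(extra) - 1, 2)]
    categories = []
    for a, b in pairs:
        ra, rb = scheme.region_of(a), scheme.region_of(b)
        # lower-position region first; a <= b already by construction
        categories.append(f"{ra}-{rb}")
    return DisulfideProfile(
        canonical_present=canonical_present,
        extra_cys=extra,
        inferred_pairs=pairs,
        pair_categories=categories,
        unpaired_flag=len(extra) % 2 == 1,
    )


def classify_salt_bridge(seq: NumberedSequence) -> SaltBridgeClass:
    """Apply the 94/101 residue rule (absent positions classify as none)."""
    r94 = seq.residue_at(ChothiaPosition(94))
    r101 = seq.residue_at(ChothiaPosition(101))
    if r94 == "R" and r101 == "D":
        return SaltBridgeClass("canonical")
    if r94 in BASIC_94 and r101 in ACIDIC_101:
        return SaltBridgeClass("noncanonical")
    return SaltBridgeClass("none")


@dataclass
class BridgeCountTable:
    """Species-level disulfide and salt-bridge count tables with totals."""

    disulfide: pd.DataFrame  # (class, species) x [no_bond, canonical, noncanonical, total]
    salt: pd.DataFrame       # (class, species) x [canonical, noncanonical, none, total]
    per_sequence: pd.DataFrame
    pair_category_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def disulfide_percentages(self, ndigits: int = 1) -> pd.DataFrame:
        pct = self.disulfide.copy()
        for col in ("no_bond", "canonical", "noncanonical"):
            pct[col] = [
                round_half_up(100.0 * v / t, ndigits) if t else float("nan")
                for v, t in zip(self.disulfide[col], self.disulfide["total"])
            ]
        return pct

    def salt_percentages(self, ndigits: int = 1) -> pd.DataFrame:
        pct = self.salt.copy()
        for col in ("canonical", "noncanonical", "none"):
            pct[col] = [
                round_half_up(100.0 * v / t, ndigits) if t else float("nan")
                for v, t in zip(self.salt[col], self.salt["total"])
            ]
        return pct


def profile_dataset(
    ds: SequenceDataset, scheme: RegionScheme | None = None
) -> BridgeCountTable:
    """Classify every sequence and aggregate per (class, species) plus totals."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    scheme = scheme or default_scheme()
    rows = []
    for rec in ds:
        prof = classify_disulfide(rec, scheme)
        salt = classify_salt_bridge(rec)
        rows.append(
            {
                "id": rec.id,
                "class": rec.domain_class,
                "species": rec.species,
                "canonical_disulfide": prof.canonical_present,
                "n_extra_cys": len(prof.extra_cys),
                "extra_pair_categories": ";".join(prof.pair_categories),
                "unpaired_cysteine": prof.unpaired_flag,
                "salt_bridge": salt.value,
            }
        )
    per_seq = pd.DataFrame(rows)

    ds_rows, salt_rows = [], []
    pair_counts: dict[str, dict[str, int]] = {}
    for domain_class in sorted(per_seq["class"].unique()):
        sub_cls = per_seq[per_seq["class"] == domain_class]
        species_list = sorted(sub_cls["species"].unique())
        for species in species_list + ["Total"]:
            sub = sub_cls if species == "Total" else sub_cls[sub_cls["species"] == species]
            n = len(sub)
            canonical = int(sub["canonical_disulfide"].sum())
            noncanonical = int(
                (sub["canonical_disulfide"] & (sub["extra_pair_categories"] != "")).sum()
            )
            ds_rows.append(
                {
                    "class": domain_class,
                    "species": species,
                    "no_bond": n - canonical,
                    "canonical": canonical,
                    "noncanonical": noncanonical,
                    "total": n,
                }
            )
            salt_rows.append(
                {
                    "class": domain_class,
                    "species": species,
                    "canonical": int((sub["salt_bridge"] == "canonical").sum()),
                    "noncanonical": int((sub["salt_bridge"] == "noncanonical").sum()),
                    "none": int((sub["salt_bridge"] == "none").sum()),
                    "total": n,
                }
            )
        cats: dict[str, int] = {}
        for labels in sub_cls["extra_pair_categories"]:
            for label in filter(None, labels.split(";")):
                cats[label] = cats.get(label, 0) + 1
        pair_counts[domain_class] = dict(
            sorted(cats.items(), key=lambda kv: _pair_sort_key(kv[0]))
        )

    disulfide = pd.DataFrame(ds_rows).set_index(["class", "species"])
    salt = pd.DataFrame(salt_rows).set_index(["class", "species"])
    return BridgeCountTable(disulfide, salt, per_seq, pair_counts)


def _pair_sort_key(label: str) -> tuple[int, int]:
    r1, _, r2 = label.partition("-")
    return (REGION_ORDER.index(r1), REGION_ORDER.index(r2))
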