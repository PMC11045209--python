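"""Per-region physicochemical composition features.

Residues are binned into the nine overlapping Pepstats-style property classes
(Tiny, Small, Aliphatic, Aromatic, Non-polar, Polar, Charged, Basic, Acidic)
plus the three mutually exclusive hydropathy classes (Hydrophilic, Neutral,
Hydrophobic).  A feature is the percentage of a region's residues falling in
a class; overlapping membership is deliberate (e.g. A is Tiny, Small,
Aliphatic and Non-polar).

Handling of ambiguity codes: X residues are excluded from both numerator and
denominator; B and Z participate in the nine property classes exactly as the
class sets define but have no hydropathy assignment, so hydropathy
denominators count only the 20 standard residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SequenceDataset
from .positions import ChothiaPosition
from .regions import RegionScheme, default_scheme, segment

PEPSTATS_CLASSES: dict[str, frozenset[str]] = {
    "Tiny": frozenset("ACGST"),
    "Small": frozenset("ABCDGNPSTV"),
    "Aliphatic": frozenset("AILV"),
    "Aromatic": frozenset("FHWY"),
    "Non-polar": frozenset("ACFGILMPVWY"),
    "Polar": frozenset("DEHKNQRSTZ"),
    "Charged": frozenset("BDEHKRZ"),
    "Basic": frozenset("HKR"),
    "Acidic": frozenset("BDEZ"),
}

HYDROPATHY_CLASSES: dict[str, frozenset[str]] = {
    "Hydrophilic": frozenset("DEKNRQ"),
    "Neutral": frozenset("GHPTSY"),
    "Hydrophobic": frozenset("ACFILMVW"),
}

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CategoryScheme:
    """Residue-class sets used for featurization."""

    classes: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(PEPSTATS_CLASSES)
    )
    hydropathy: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(HYDROPATHY_CLASSES)
    )

    def class_names(self) -> list[str]:
        return list(self.classes) + list(self.hydropathy)

    def members(self, name: str) -> frozenset[str]:
        if name in self.classes:
            return self.classes[name]
        return self.hydropathy[name]


def default_categories() -> CategoryScheme:
    return CategoryScheme()


def category_percentages(
    residues: str, scheme: CategoryScheme | None = None
) -> dict[str, float] | None:
    """Percentage of residues in each class; None for empty / all-X input."""
    scheme = scheme or default_categories()
    kept = [r for r in residues if r != "X"]
    if not kept:
        return None
    n = len(kept)
    out = {
        name: 100.0 * sum(r in members for r in kept) / n
        for name, members in scheme.classes.items()
    }
    standard = [r for r in kept if r in STANDARD_RESIDUES]
    for name, members in scheme.hydropathy.items():
        out[name] = (
            100.0 * sum(r in members for r in standard) / len(standard)
            if standard
            else float("nan")
        )
    return out


FW_REGIONS = ("FW1", "FW2", "FW3", "FW4")
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def build_feature_table(
    ds: SequenceDataset,
    categories: CategoryScheme | None = None,
    regions: tuple[str, ...] = FW_REGIONS,
    include_aa_freqs: bool = False,
    region_scheme: RegionScheme | None = None,
) -> pd.DataFrame:
    """Per-sequence feature table: ``<region>_<Class>`` percentages + label.

    The label column encodes the domain class (VH=0, VHH=1).  Regions that
    are entirely missing (or all-X) in a sequence propagate as NaN cells.
    """
    categories = categories or default_categories()
    region_scheme = region_scheme or default_scheme()
    if len(ds.classes()) < 2:
        import warnings

        warnings.warn("feature table has fewer than two classes; downstream "
                      "classification models need both VH and VHH rows")
    rows = []
    for rec in ds:
        parts = segment(rec, region_scheme)
        row: dict[str, object] = {
            "id": rec.id,
            "species": rec.species,
            "label": 0 if rec.domain_class == "VH" else 1,
        }
        for region in regions:
            residues = "".join(res for _, res in parts[region])
            pcts = category_percentages(residues, categories)
            for name in categories.class_names():
                row[f"{region}_{name}"] = pcts[name] if pcts else np.nan
            if include_aa_freqs:
                kept = [r for r in residues if r != "X"]
                n = len(kept)
                for aa in AA_ORDER:
                    row[f"{region}_{aa}"] = (
                        100.0 * kept.count(aa) / n if n else np.nan
                    )
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The numeric feature columns of a feature table."""
    return [c for c in table.columns if c not in ("species", "label")]


def residue_class_difference(
    ds: SequenceDataset,
    categories: CategoryScheme | None = None,
    clip: float = 50.0,
) -> pd.DataFrame:
    """Per-(position, class) signed VHH-minus-VH membership difference.

    For each Chothia position and residue class, computes the percentage of
    VHH sequences whose residue at the position belongs to the class minus
    the same percentage for VH (denominators are the sequences occupying the
    position).  Differences are clipped to ±``clip`` for heatmap export;
    positions occupied in only one class are flagged alternating and carry no
    difference.
    """
    categories = categories or default_categories()
    classes = ds.classes()
    if set(classes) != {"VH", "VHH"}:
        raise ValueError("residue_class_difference requires both VH and VHH sequences")

    occupants: dict[ChothiaPosition, dict[str, list[str]]] = {}
    for rec in ds:
        for pos, res in rec.items():
            if res == "X":
                continue
            occupants.setdefault(pos, {"VH": [], "VHH": []})[rec.domain_class].append(res)

    names = categories.class_names()
    rows = []
    for pos in sorted(occupants, key=lambda p: p.sort_key()):
        vh, vhh = occupants[pos]["VH"], occupants[pos]["VHH"]
        alternating = not vh or not vhh
        for name in names:
            members = categories.members(name)
            if alternating:
                diff = np.nan
            else:
                pct_vhh = 100.0 * sum(r in members for r in vhh) / len(vhh)
                pct_vh = 100.0 * sum(r in members for r in vh) / len(vh)
                diff = float(np.clip(pct_vhh - pct_vh, -clip, clip))
            rows.append(
                {
                    "position": pos.label,
                    "class": name,
                    "difference": diff,
                    "alternating": alternating,
                }
            )
    return pd.DataFrame(rows)
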