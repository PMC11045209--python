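"""Synthetic VH/VHH repertoire generator.

Emulates the statistical structure of curated heavy-chain variable-domain
repertoires (mammalian VH from abYsis-style surveys, camelid VHH from
sdAb-DB-style surveys): two labelled classes with configurable per-species
HCDR length distributions, framework consensus strings with hallmark FW2
motifs (VGLW in VH vs FERF/YERF in VHH), controlled residues at the
salt-bridge landmarks 94/101, and controlled cysteine placement for
canonical (22-92) and extra ("noncanonical") disulfide pairs.

Two sampling modes per trait mix:

* **proportion mode** — mix values are floats summing to 1; each sequence
  draws its trait class independently;
* **exact-count mode** — mix values are ints summing to the species total;
  the generated dataset reproduces those counts deterministically, so a
  downstream classifier recovers them with zero error.

Randomness is split per sequence from the master seed (class, species,
index), so adding a record never reshuffles the others.  Background noise
never introduces cysteines: C appears only where the disulfide mix places
it, which is what makes exact-count disulfide tables exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import NumberedSequence, SequenceDataset
from .positions import ChothiaPosition
from .regions import DEFAULT_WINDOWS, REGION_ORDER, RegionScheme, default_scheme

__all__ = [
    "GeneratorConfig",
    "ClassConfig",
    "SpeciesBlock",
    "GeneratorError",
    "generate",
    "default_vh_config",
    "default_vhh_config",
    "default_config",
    "reference_vh_config",
    "reference_vhh_config",
    "reference_config",
    "VH_REFERENCE_COUNTS",
    "VHH_REFERENCE_COUNTS",
]


class GeneratorError(ValueError):
    """Invalid or unsatisfiable generator configuration."""


SALT_CLASSES = ("canonical", "noncanonical", "none")
DISULFIDE_CLASSES = ("no_bond", "canonical_only", "canonical_plus_noncanonical")

#: landmark base numbers never used for extra-cysteine placement or noise
LANDMARK_BASES = frozenset({22, 92, 94, 101, 103})

HALLMARK_POSITIONS = (37, 44, 45, 47)

#: background substitution alphabet — 19 letters, cysteine deliberately absent
NOISE_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

#: residue pool for hypervariable loop positions (no cysteine)
_CDR_LETTERS = np.array(list("GSYDNARTFWVILPHKEQM"))
_CDR_WEIGHTS = np.array(
    [0.13, 0.12, 0.10, 0.08, 0.06, 0.08, 0.07, 0.07, 0.05, 0.04,
     0.04, 0.04, 0.03, 0.03, 0.02, 0.02, 0.01, 0.005, 0.005]
)
_CDR_WEIGHTS = _CDR_WEIGHTS / _CDR_WEIGHTS.sum()

#: non-canonical salt-bridge residue combinations at (94, 101): basic x acidic
#: minus the canonical R-D pair
_NONCANONICAL_SALT = [("R", "E"), ("K", "D"), ("K", "E"), ("H", "D"), ("H", "E")]

#: rule-negative residue pools for the "none" salt-bridge class; alanine is
#: favoured at 94 because it dominates that position in camelid VHHs
_NONE_94_LETTERS = np.array(list("AGSTV"))
_NONE_94_WEIGHTS = np.array([0.6, 0.1, 0.1, 0.1, 0.1])
_NONE_101_LETTERS = np.array(list("GSTNQ"))

#: anchor base number receiving insertion letters when a loop is longer than
#: its base window
_INSERTION_ANCHOR = {"HCDR1": 31, "HCDR2": 52, "HCDR3": 100}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SpeciesBlock:
    """Per-species slice of a class: size plus optional trait-mix overrides."""

    count: int | None = None
    weight: float | None = None
    salt_bridge_mix: dict[str, float] | None = None
    disulfide_mix: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if (self.count is None) == (self.weight is None):
            raise GeneratorError("species block needs exactly one of count / weight")
        if self.count is not None and (not isinstance(self.count, int) or self.count < 0):
            raise GeneratorError(f"species count must be a nonnegative int, got {self.count!r}")
        if self.weight is not None and self.weight < 0:
            raise GeneratorError("species weight must be nonnegative")


def _check_mix(mix: Mapping[str, float], allowed: tuple[str, ...], what: str,
               total: int | None = None) -> bool:
    """Validate a trait mix; returns True when it is exact-count (all ints)."""
    unknown = set(mix) - set(allowed)
    if unknown:
        raise GeneratorError(f"{what}: unknown keys {sorted(unknown)}; allowed {allowed}")
    values = list(mix.values())
    exact = all(isinstance(v, (int, np.integer)) and not isinstance(v, bool) for v in values)
    if exact:
        if any(v < 0 for v in values):
            raise GeneratorError(f"{what}: negative count")
        if total is not None and sum(values) != total:
            raise GeneratorError(
                f"{what}: exact counts sum to {sum(values)}, species total is {total}"
            )
    else:
        if any(v < 0 for v in values):
            raise GeneratorError(f"{what}: negative proportion")
        if abs(sum(values) - 1.0) > 1e-9:
            raise GeneratorError(f"{what}: proportions sum to {sum(values)!r}, expected 1")
    return exact


@dataclass
class ClassConfig:
    """Generator block for one domain class (VH or VHH)."""

    domain_class: str
    species: dict[str, SpeciesBlock]
    hcdr_length_dists: dict[str, dict[int, float]]
    fw_consensus: dict[str, str]
    hallmark_motifs: dict[str, float]
    salt_bridge_mix: dict[str, float]
    disulfide_mix: dict[str, float]
    noncanonical_pair_dist: dict[str, float]
    background_keep: float = 0.8
    hallmark_keep: float = 0.95

    def __post_init__(self) -> None:
        if self.domain_class not in ("VH", "VHH"):
            raise GeneratorError(f"domain_class must be VH or VHH, got {self.domain_class!r}")
        if not self.species:
            raise GeneratorError("at least one species block required")
        for region, consensus in self.fw_consensus.items():
            lo, hi = DEFAULT_WINDOWS[region]
            if len(consensus) != hi - lo + 1:
                raise GeneratorError(
                    f"{region} consensus length {len(consensus)} != window width {hi - lo + 1}"
                )
        for region, dist in self.hcdr_length_dists.items():
            if region not in ("HCDR1", "HCDR2", "HCDR3"):
                raise GeneratorError(f"length distribution for unknown region {region!r}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise GeneratorError(f"{region} length probabilities must sum to 1")
            if any(length < 0 for length in dist):
                raise GeneratorError(f"{region} length must be nonnegative")
        if abs(sum(self.hallmark_motifs.values()) - 1.0) > 1e-9:
            raise GeneratorError("hallmark motif weights must sum to 1")
        if any(len(m) != len(HALLMARK_POSITIONS) for m in self.hallmark_motifs):
            raise GeneratorError("hallmark motifs must cover positions 37/44/45/47")
        if abs(sum(self.noncanonical_pair_dist.values()) - 1.0) > 1e-9:
            raise GeneratorError("noncanonical pair weights must sum to 1")
        for label in self.noncanonical_pair_dist:
            r1, _, r2 = label.partition("-")
            if r1 not in REGION_ORDER or r2 not in REGION_ORDER:
                raise GeneratorError(f"unknown region pair label {label!r}")
        _check_mix(self.salt_bridge_mix, SALT_CLASSES, "class salt_bridge_mix")
        _check_mix(self.disulfide_mix, DISULFIDE_CLASSES, "class disulfide_mix")

    def exact_counts(self) -> bool:
        return all(b.count is not None for b in self.species.values())

    def total(self) -> int | None:
        if self.exact_counts():
            return sum(b.count for b in self.species.values())
        return None


@dataclass
class GeneratorConfig:
    """Two-class generator configuration with a default master seed."""

    vh: ClassConfig | None = None
    vhh: ClassConfig | None = None
    seed: int = 0

    def class_configs(self) -> dict[str, ClassConfig]:
        out = {}
        if self.vh is not None:
            out["VH"] = self.vh
        if self.vhh is not None:
            out["VHH"] = self.vhh
        if not out:
            raise GeneratorError("config defines no class blocks")
        return out


# ---------------------------------------------------------------------------
# generation


def _apportion(weights: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n sequences over species weights."""
    total_w = sum(weights.values())
    if total_w <= 0:
        raise GeneratorError("species weights sum to zero")
    quotas = {s: n * w / total_w for s, w in weights.items()}
    counts = {s: int(np.floor(q)) for s, q in quotas.items()}
    remainder = n - sum(counts.values())
    order = sorted(weights, key=lambda s: (-(quotas[s] - counts[s]), s))
    for s in order[:remainder]:
        counts[s] += 1
    return counts


def _label_stream(mix: Mapping[str, float], allowed: tuple[str, ...], total: int,
                  rng: np.random.Generator, what: str) -> list[str]:
    """Materialize trait labels for a species: exact counts or i.i.d. draws."""
    exact = _check_mix(mix, allowed, what, total if _is_exact(mix) else None)
    if exact:
        labels: list[str] = []
        for cls in allowed:
            labels.extend([cls] * int(mix.get(cls, 0)))
        rng.shuffle(labels)
        return labels
    probs = np.array([mix.get(cls, 0.0) for cls in allowed], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(allowed), size=total, p=probs)
    return [allowed[i] for i in idx]


def _is_exact(mix: Mapping[str, float]) -> bool:
    return all(
        isinstance(v, (int, np.integer)) and not isinstance(v, bool)
        for v in mix.values()
    )


def _occupied_loop_positions(region: str, length: int) -> list[ChothiaPosition]:
    """Occupied positions of a loop of a given length.

    Short loops vacate the middle of the base window (filled from both ends),
    matching how Chothia deletions are placed; long loops add insertion
    letters at the region's anchor position (31, 52 or 100).
    """
    lo, hi = DEFAULT_WINDOWS[region]
    base = list(range(lo, hi + 1))
    k = len(base)
    if length <= k:
        head = (length + 1) // 2
        tail = length - head
        numbers = base[:head] + (base[k - tail:] if tail else [])
        return [ChothiaPosition(n) for n in numbers]
    n_ins = length - k
    if n_ins > 26:
        raise GeneratorError(f"{region} length {length} exceeds the insertion-letter range")
    anchor = _INSERTION_ANCHOR[region]
    out = [ChothiaPosition(n) for n in base if n <= anchor]
    out += [ChothiaPosition(anchor, chr(ord("A") + i)) for i in range(n_ins)]
    out += [ChothiaPosition(n) for n in base if n > anchor]
    return out


def _draw_categorical(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(keys[rng.choice(len(keys), p=probs / probs.sum())])


def _noise_residue(consensus: str, rng: np.random.Generator) -> str:
    alts = [c for c in NOISE_ALPHABET if c != consensus]
    return alts[rng.integers(len(alts))]


def _build_sequence(
    cfg: ClassConfig,
    sid: str,
    species: str,
    salt_label: str,
    ds_label: str,
    pair_label: str | None,
    rng: np.random.Generator,
) -> NumberedSequence:
    residues: dict[ChothiaPosition, str] = {}

    # framework scaffold: consensus with background substitution (never C)
    for region in ("FW1", "FW2", "FW3", "FW4"):
        consensus = cfg.fw_consensus[region]
        lo, _ = DEFAULT_WINDOWS[region]
        keep = rng.random(len(consensus)) < cfg.background_keep
        for offset, cons in enumerate(consensus):
            number = lo + offset
            if number in LANDMARK_BASES and number != 103:
                continue  # controlled below
            if number == 103:
                # conserved FW4 tryptophan, still subject to mild noise
                res = cons if keep[offset] else _noise_residue(cons, rng)
            else:
                res = cons if keep[offset] else _noise_residue(cons, rng)
            residues[ChothiaPosition(number)] = res

    # hallmark FW2 motif at 37/44/45/47
    motifs = sorted(cfg.hallmark_motifs)
    weights = np.array([cfg.hallmark_motifs[m] for m in motifs], dtype=float)
    motif = motifs[rng.choice(len(motifs), p=weights / weights.sum())]
    for number, cons in zip(HALLMARK_POSITIONS, motif):
        res = cons if rng.random() < cfg.hallmark_keep else _noise_residue(cons, rng)
        residues[ChothiaPosition(number)] = res

    # hypervariable loops
    for region in ("HCDR1", "HCDR2", "HCDR3"):
        length = _draw_categorical(cfg.hcdr_length_dists[region], rng)
        positions = _occupied_loop_positions(region, length)
        if positions:
            draws = rng.choice(len(_CDR_LETTERS), size=len(positions), p=_CDR_WEIGHTS)
            for pos, di in zip(positions, draws):
                residues[pos] = str(_CDR_LETTERS[di])

    # canonical disulfide landmarks
    if ds_label == "no_bond":
        residues[ChothiaPosition(22)] = "S"
        residues[ChothiaPosition(92)] = "A"
    else:
        residues[ChothiaPosition(22)] = "C"
        residues[ChothiaPosition(92)] = "C"

    # salt-bridge landmarks 94 / 101
    pos94, pos101 = ChothiaPosition(94), ChothiaPosition(101)
    if salt_label in ("canonical", "noncanonical") and pos101 not in residues:
        raise GeneratorError(
            f"{sid}: salt-bridge class {salt_label!r} requires position 101, "
            "but the drawn HCDR3 is too short to occupy it"
        )
    if salt_label == "canonical":
        residues[pos94], residues[pos101] = "R", "D"
    elif salt_label == "noncanonical":
        r94, r101 = _NONCANONICAL_SALT[rng.integers(len(_NONCANONICAL_SALT))]
        residues[pos94], residues[pos101] = r94, r101
    else:
        residues[pos94] = str(_NONE_94_LETTERS[rng.choice(5, p=_NONE_94_WEIGHTS)])
        if pos101 in residues:
            residues[pos101] = str(_NONE_101_LETTERS[rng.integers(5)])

    # extra cysteine pair for the noncanonical disulfide class
    if ds_label == "canonical_plus_noncanonical":
        if pair_label is None:
            raise GeneratorError(f"{sid}: noncanonical disulfide requested without a region pair")
        r1, _, r2 = pair_label.partition("-")
        ordered = sorted(residues, key=lambda p: p.sort_key())

        def eligible(region: str) -> list[ChothiaPosition]:
            lo, hi = DEFAULT_WINDOWS[region]
            return [
                p for p in ordered
                if lo <= p.number <= hi
                and p.number not in LANDMARK_BASES
                and residues[p] != "C"
            ]

        if r1 == r2:
            slots = eligible(r1)[:2]
        else:
            e1, e2 = eligible(r1), eligible(r2)
            slots = (e1[:1] + e2[:1]) if (e1 and e2) else []
        if len(slots) < 2:
            raise GeneratorError(
                f"{sid}: region pair {pair_label} cannot host an extra cysteine pair"
            )
        for p in slots:
            residues[p] = "C"

    return NumberedSequence(sid, species, cfg.domain_class, residues)


def _species_slug(species: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in species)


def generate(
    config: GeneratorConfig,
    n_per_class: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> SequenceDataset:
    """Sample a labelled VH/VHH dataset from a generator configuration.

    ``n_per_class`` is required for proportion-mode class blocks and must
    match the configured totals for exact-count blocks when given.  The same
    (config, seed) pair always yields a bit-identical dataset.
    """
    master = config.seed if seed is None else seed
    records: list[NumberedSequence] = []
    for class_idx, (domain_class, cfg) in enumerate(sorted(config.class_configs().items())):
        if cfg.exact_counts():
            counts = {s: b.count for s, b in cfg.species.items()}
            if n_per_class is not None and domain_class in n_per_class:
                requested = n_per_class[domain_class]
                if requested != sum(counts.values()):
                    raise GeneratorError(
                        f"{domain_class}: requested n={requested} but exact species "
                        f"counts sum to {sum(counts.values())}"
                    )
        else:
            if n_per_class is None or domain_class not in n_per_class:
                raise GeneratorError(
                    f"{domain_class}: proportion-mode config needs n_per_class"
                )
            weights = {s: b.weight for s, b in cfg.species.items()}
            counts = _apportion(weights, int(n_per_class[domain_class]))

        for species in sorted(cfg.species):
            block = cfg.species[species]
            total = counts[species]
            if total == 0:
                continue
            crc = zlib.crc32(species.encode("utf-8"))
            species_rng = np.random.default_rng(
                np.random.SeedSequence(master, spawn_key=(class_idx, crc, 0xFFFFFFFF))
            )
            salt_mix = block.salt_bridge_mix or cfg.salt_bridge_mix
            ds_mix = block.disulfide_mix or cfg.disulfide_mix
            salt_labels = _label_stream(
                salt_mix, SALT_CLASSES, total, species_rng,
                f"{domain_class}/{species} salt_bridge_mix",
            )
            ds_labels = _label_stream(
                ds_mix, DISULFIDE_CLASSES, total, species_rng,
                f"{domain_class}/{species} disulfide_mix",
            )
            pair_labels = sorted(cfg.noncanonical_pair_dist)
            pair_weights = np.array(
                [cfg.noncanonical_pair_dist[p] for p in pair_labels], dtype=float
            )
            pair_weights = pair_weights / pair_weights.sum()
            slug = _species_slug(species)
            for i in range(total):
                rng = np.random.default_rng(
                    np.random.SeedSequence(master, spawn_key=(class_idx, crc, i))
                )
                pair = None
                if ds_labels[i] == "canonical_plus_noncanonical":
                    pair = pair_labels[int(rng.choice(len(pair_labels), p=pair_weights))]
                sid = f"{domain_class}_{slug}_{i:05d}"
                records.append(
                    _build_sequence(cfg, sid, species, salt_labels[i], ds_labels[i], pair, rng)
                )
    return SequenceDataset(
        records,
        provenance={"generator": "vhhprof.synthetic", "seed": str(master)},
    )


# ---------------------------------------------------------------------------
# default study conditions

_VH_FW_CONSENSUS = {
    "FW1": "EVQLVESGGGLVQPGGSLRLSCAAS",
    "FW2": "AMSWVRQAPGKGLEWVSAI",
    "FW3": "TYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTACAR",
    "FW4": "WGQGTLVTVSS",
}

_VHH_FW_CONSENSUS = {
    "FW1": "QVQLVESGGGLVQPGGSLRLSCAAS",
    "FW2": "AMGWFRQAPGKEREFVSAI",
    "FW3": "TYYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTACAA",
    "FW4": "WGQGTQVTVSS",
}

#: unimodal HCDR length distributions; HCDR3 modes 10 (VH) and 15 (VHH)
_VH_LENGTHS = {
    "HCDR1": {5: 0.05, 6: 0.10, 7: 0.70, 8: 0.10, 9: 0.05},
    "HCDR2": {4: 0.05, 5: 0.25, 6: 0.60, 7: 0.10},
    "HCDR3": {7: 0.05, 8: 0.10, 9: 0.20, 10: 0.28, 11: 0.15,
              12: 0.10, 13: 0.06, 14: 0.03, 15: 0.02, 16: 0.01},
}
_VHH_LENGTHS = {
    "HCDR1": {5: 0.08, 6: 0.15, 7: 0.62, 8: 0.10, 9: 0.05},
    "HCDR2": {4: 0.05, 5: 0.30, 6: 0.55, 7: 0.10},
    "HCDR3": {10: 0.03, 11: 0.05, 12: 0.08, 13: 0.10, 14: 0.14, 15: 0.22,
              16: 0.14, 17: 0.10, 18: 0.07, 19: 0.04, 20: 0.03},
}

_VH_PAIRS = {
    "HCDR1-HCDR2": 0.25, "HCDR1-HCDR3": 0.25,
    "FW2-HCDR2": 0.25, "HCDR3-HCDR3": 0.25,
}
_VHH_PAIRS = {"HCDR1-HCDR3": 1 / 3, "FW2-HCDR3": 1 / 3, "HCDR3-HCDR3": 1 / 3}

#: reference per-species composition of curated repertoires: for each species,
#: total sequences, disulfide counts (no bond / canonical / noncanonical,
#: where "noncanonical" sequences also carry the canonical bond) and
#: salt-bridge counts (canonical / noncanonical / none)
VH_REFERENCE_COUNTS: dict[str, dict] = {
    "Cricetulus migratorius":          {"total": 10,   "disulfide": (0, 10, 0),      "salt": (5, 0, 5)},
    "Homo sapiens":                    {"total": 2457, "disulfide": (1, 2456, 130),  "salt": (1409, 282, 766)},
    "Homo sapiens/Mus musculus":       {"total": 26,   "disulfide": (0, 26, 0),      "salt": (10, 0, 16)},
    "Mus musculus":                    {"total": 2290, "disulfide": (3, 2287, 2),    "salt": (1291, 44, 955)},
    "Mus musculus/Homo sapiens":       {"total": 188,  "disulfide": (0, 188, 0),     "salt": (80, 5, 103)},
    "Pan troglodytes":                 {"total": 4,    "disulfide": (0, 4, 0),       "salt": (4, 0, 0)},
    "Rattus norvegicus":               {"total": 53,   "disulfide": (0, 53, 0),      "salt": (32, 10, 11)},
    "Rattus norvegicus/Homo sapiens":  {"total": 2,    "disulfide": (0, 2, 0),       "salt": (0, 2, 0)},
}

VHH_REFERENCE_COUNTS: dict[str, dict] = {
    "Camelidae":           {"total": 65,  "disulfide": (0, 65, 3),    "salt": (0, 0, 65)},
    "Camelus bactrianus":  {"total": 63,  "disulfide": (0, 63, 4),    "salt": (0, 1, 62)},
    "Camelus dromedarius": {"total": 263, "disulfide": (0, 263, 26),  "salt": (2, 0, 261)},
    "Lama glama":          {"total": 670, "disulfide": (1, 669, 16),  "salt": (12, 13, 645)},
    "Vicugna pacos":       {"total": 199, "disulfide": (0, 199, 20),  "salt": (5, 2, 192)},
}


def _reference_species_blocks(table: dict[str, dict]) -> dict[str, SpeciesBlock]:
    blocks = {}
    for species, row in table.items():
        no_bond, canonical, noncanonical = row["disulfide"]
        if no_bond + canonical != row["total"] or noncanonical > canonical:
            raise GeneratorError(f"inconsistent disulfide counts for {species}")
        can_sb, noncan_sb, none_sb = row["salt"]
        blocks[species] = SpeciesBlock(
            count=row["total"],
            salt_bridge_mix={
                "canonical": can_sb, "noncanonical": noncan_sb, "none": none_sb,
            },
            disulfide_mix={
                "no_bond": no_bond,
                "canonical_only": canonical - noncanonical,
                "canonical_plus_noncanonical": noncanonical,
            },
        )
    return blocks


def _weight_blocks(table: dict[str, dict]) -> dict[str, SpeciesBlock]:
    total = sum(row["total"] for row in table.values())
    return {s: SpeciesBlock(weight=row["total"] / total) for s, row in table.items()}


def _aggregate_mixes(table: dict[str, dict]) -> tuple[dict[str, float], dict[str, float]]:
    total = sum(row["total"] for row in table.values())
    can_sb = sum(row["salt"][0] for row in table.values())
    noncan_sb = sum(row["salt"][1] for row in table.values())
    none_sb = sum(row["salt"][2] for row in table.values())
    no_bond = sum(row["disulfide"][0] for row in table.values())
    noncan_ds = sum(row["disulfide"][2] for row in table.values())
    can_only = total - no_bond - noncan_ds
    salt = {"canonical": can_sb / total, "noncanonical": noncan_sb / total,
            "none": none_sb / total}
    ds = {"no_bond": no_bond / total, "canonical_only": can_only / total,
          "canonical_plus_noncanonical": noncan_ds / total}
    return salt, ds


def default_vh_config() -> ClassConfig:
    """Proportion-mode VH block reflecting the reference repertoire rates."""
    salt, ds = _aggregate_mixes(VH_REFERENCE_COUNTS)
    return ClassConfig(
        domain_class="VH",
        species=_weight_blocks(VH_REFERENCE_COUNTS),
        hcdr_length_dists={k: dict(v) for k, v in _VH_LENGTHS.items()},
        fw_consensus=dict(_VH_FW_CONSENSUS),
        hallmark_motifs={"VGLW": 1.0},
        salt_bridge_mix=salt,
        disulfide_mix=ds,
        noncanonical_pair_dist=dict(_VH_PAIRS),
    )


def default_vhh_config() -> ClassConfig:
    """Proportion-mode VHH block reflecting the reference repertoire rates."""
    salt, ds = _aggregate_mixes(VHH_REFERENCE_COUNTS)
    return ClassConfig(
        domain_class="VHH",
        species=_weight_blocks(VHH_REFERENCE_COUNTS),
        hcdr_length_dists={k: dict(v) for k, v in _VHH_LENGTHS.items()},
        fw_consensus=dict(_VHH_FW_CONSENSUS),
        hallmark_motifs={"FERF": 0.6, "YERF": 0.4},
        salt_bridge_mix=salt,
        disulfide_mix=ds,
        noncanonical_pair_dist=dict(_VHH_PAIRS),
    )


def reference_vh_config() -> ClassConfig:
    """Exact-count VH block reproducing the reference per-species tables."""
    cfg = default_vh_config()
    cfg.species = _reference_species_blocks(VH_REFERENCE_COUNTS)
    return cfg


def reference_vhh_config() -> ClassConfig:
    """Exact-count VHH block reproducing the reference per-species tables."""
    cfg = default_vhh_config()
    cfg.species = _reference_species_blocks(VHH_REFERENCE_COUNTS)
    return cfg


def default_config(seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(vh=default_vh_config(), vhh=default_vhh_config(), seed=seed)


def reference_config(seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(vh=reference_vh_config(), vhh=reference_vhh_config(), seed=seed)


# ---------------------------------------------------------------------------
# (de)serialization for CLI configs


def config_to_dict(config: GeneratorConfig) -> dict:
    def block(cfg: ClassConfig | None):
        if cfg is None:
            return None
        return {
            "domain_class": cfg.domain_class,
            "species": {
                s: {k: v for k, v in vars(b).items() if v is not None}
                for s, b in cfg.species.items()
            },
            "hcdr_length_dists": {
                r: {int(k): float(v) for k, v in d.items()}
                for r, d in cfg.hcdr_length_dists.items()
            },
            "fw_consensus": dict(cfg.fw_consensus),
            "hallmark_motifs": dict(cfg.hallmark_motifs),
            "salt_bridge_mix": dict(cfg.salt_bridge_mix),
            "disulfide_mix": dict(cfg.disulfide_mix),
            "noncanonical_pair_dist": dict(cfg.noncanonical_pair_dist),
            "background_keep": cfg.background_keep,
            "hallmark_keep": cfg.hallmark_keep,
        }

    return {"seed": config.seed, "vh": block(config.vh), "vhh": block(config.vhh)}


def config_from_dict(data: Mapping) -> GeneratorConfig:
    def block(d):
        if d is None:
            return None
        species = {s: SpeciesBlock(**b) for s, b in d["species"].items()}
        return ClassConfig(
            domain_class=d["domain_class"],
            species=species,
            hcdr_length_dists={
                r: {int(k): float(v) for k, v in dist.items()}
                for r, dist in d["hcdr_length_dists"].items()
            },
            fw_consensus=dict(d["fw_consensus"]),
            hallmark_motifs=dict(d["hallmark_motifs"]),
            salt_bridge_mix=dict(d["salt_bridge_mix"]),
            disulfide_mix=dict(d["disulfide_mix"]),
            noncanonical_pair_dist=dict(d["noncanonical_pair_dist"]),
            background_keep=float(d.get("background_keep", 0.8)),
            hallmark_keep=float(d.get("hallmark_keep", 0.95)),
        )

    return GeneratorConfig(
        vh=block(data.get("vh")), vhh=block(data.get("vhh")),
        seed=int(data.get("seed", 0)),
    )
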