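"""Disulfide and salt-bridge rule classification and aggregation."""

import itertools

import pytest

from vhhprof import (
    SequenceDataset,
    classify_disulfide,
    classify_salt_bridge,
    default_config,
    generate,
    profile_dataset,
)
from vhhprof.bridges import round_half_up

from conftest import seq


# -- salt-bridge rule --------------------------------------------------------

@pytest.mark.parametrize(
    "r94, r101, expected",
    [
        ("R", "D", "canonical"),
        ("K", "E", "noncanonical"),
        ("R", "E", "noncanonical"),
        ("H", "D", "noncanonical"),
        ("A", "D", "none"),
        ("R", "S", "none"),
        (None, "D", "none"),
        ("R", None, "none"),
    ],
)
def test_salt_bridge_rule_examples(r94, r101, expected):
    pairs = [(p, r) for p, r in [("94", r94), ("101", r101)] if r is not None]
    assert classify_salt_bridge(seq("s", pairs)).value == expected


def test_salt_bridge_rule_matches_exhaustive_oracle():
    """The rule agrees with brute-force enumeration of all residue pairs
    at (94, 101), including the absent-position case (21 x 21 states)."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWY") + [None]
    for r94, r101 in itertools.product(alphabet, repeat=2):
        if r94 == "R" and r101 == "D":
            expected = "canonical"
        elif r94 in ("R", "K", "H") and r101 in ("D", "E"):
            expected = "noncanonical"
        else:
            expected = "none"
        pairs = [(p, r) for p, r in [("94", r94), ("101", r101)] if r is not None]
        assert classify_salt_bridge(seq("s", pairs)).value == expected, (r94, r101)


# -- disulfide rule ----------------------------------------------------------

def test_canonical_only():
    prof = classify_disulfide(seq("s", [("22", "C"), ("92", "C")]))
    assert prof.canonical_present
    assert prof.extra_cys == [] and prof.inferred_pairs == []
    assert not prof.unpaired_flag


def test_extra_pair_region_category():
    prof = classify_disulfide(
        seq("s", [("22", "C"), ("92", "C"), ("33", "C"), ("100", "C")])
    )
    assert prof.canonical_present
    assert prof.pair_categories == ["FW2-HCDR3"]


def test_missing_landmark_cysteine_means_no_bond():
    prof = classify_disulfide(seq("s", [("22", "C")]))
    assert not prof.canonical_present


def test_odd_cysteine_count_sets_unpaired_flag():
    prof = classify_disulfide(
        seq("s", [("22", "C"), ("92", "C"), ("26", "C"), ("96", "C"), ("100", "C")])
    )
    assert prof.unpaired_flag
    assert prof.inferred_pairs == [tuple(prof.extra_cys[:2])]
    assert prof.pair_categories == ["HCDR1-HCDR3"]


def test_profile_invariant_to_residue_storage_order():
    pairs = [("100", "C"), ("22", "C"), ("33", "C"), ("92", "C")]
    a = classify_disulfide(seq("a", pairs))
    b = classify_disulfide(seq("b", list(reversed(pairs))))
    assert a.pair_categories == b.pair_categories == ["FW2-HCDR3"]


# -- aggregation -------------------------------------------------------------

def test_salt_classes_partition_and_noncanonical_disulfide_is_subset():
    ds = generate(default_config(), {"VH": 120, "VHH": 120}, seed=23)
    table = profile_dataset(ds)
    salt = table.salt
    assert (
        salt["canonical"] + salt["noncanonical"] + salt["none"] == salt["total"]
    ).all()
    disulfide = table.disulfide
    assert (disulfide["no_bond"] + disulfide["canonical"] == disulfide["total"]).all()
    assert (disulfide["noncanonical"] <= disulfide["canonical"]).all()


def test_per_species_rows_only_for_present_species(mixed_dataset):
    table = profile_dataset(mixed_dataset)
    assert ("VH", "Lama glama") not in table.salt.index
    assert ("VHH", "Lama glama") in table.salt.index
    row = table.salt.loc[("VH", "Total")]
    assert (row["canonical"], row["noncanonical"], row["none"]) == (1, 1, 0)


def test_percentages_round_half_up():
    assert round_half_up(2.65, 1) == 2.7
    assert round_half_up(56.28, 0) == 56.0
    assert round_half_up(10.05, 1) == 10.1
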