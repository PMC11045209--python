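"""Physicochemical category percentages, feature tables and difference maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhhprof import (
    SequenceDataset,
    build_feature_table,
    category_percentages,
    default_categories,
    residue_class_difference,
)
from vhhprof.physchem import HYDROPATHY_CLASSES, PEPSTATS_CLASSES, STANDARD_RESIDUES

from conftest import seq

residue_strings = st.text(alphabet="ACDEFGHIKLMNPQRSTVWYBZX", min_size=1, max_size=40)


def test_class_set_structure():
    covered = set().union(*HYDROPATHY_CLASSES.values())
    assert covered == STANDARD_RESIDUES
    for a, b in [("Hydrophilic", "Neutral"), ("Hydrophilic", "Hydrophobic"),
                 ("Neutral", "Hydrophobic")]:
        assert not (HYDROPATHY_CLASSES[a] & HYDROPATHY_CLASSES[b])
    assert PEPSTATS_CLASSES["Basic"] | PEPSTATS_CLASSES["Acidic"] <= PEPSTATS_CLASSES["Charged"]
    assert PEPSTATS_CLASSES["Tiny"] <= PEPSTATS_CLASSES["Small"]


def test_hand_counted_examples():
    pcts = category_percentages("KRH")
    assert pcts["Basic"] == 100 and pcts["Charged"] == 100 and pcts["Acidic"] == 0
    pcts = category_percentages("AG")
    assert pcts["Tiny"] == 100 and pcts["Small"] == 100 and pcts["Non-polar"] == 100
    assert pcts["Hydrophobic"] == 50  # A hydrophobic, G neutral


def test_fw4_hydrophilic_fraction_by_hand():
    pcts = category_percentages("WGQGTQVTVSS")
    assert pcts["Hydrophilic"] == pytest.approx(100 * 2 / 11)


def test_empty_or_all_x_is_missing():
    assert category_percentages("") is None
    assert category_percentages("XXX") is None


def test_x_excluded_from_both_sides():
    assert category_percentages("KX")["Basic"] == 100


def test_bz_in_property_classes_but_not_hydropathy_denominator():
    pcts = category_percentages("KB")
    assert pcts["Charged"] == 100  # both K and B charged
    assert pcts["Acidic"] == 50
    assert pcts["Hydrophilic"] == 100  # only K counts for hydropathy
    assert math.isnan(category_percentages("BZ")["Hydrophilic"])


@settings(derandomize=True, max_examples=150)
@given(residue_strings)
def test_percentages_match_membership_oracle_and_are_permutation_invariant(s):
    scheme = default_categories()
    pcts = category_percentages(s, scheme)
    kept = [r for r in s if r != "X"]
    if not kept:
        assert pcts is None
        return
    for name, members in PEPSTATS_CLASSES.items():
        expected = 100 * sum(r in members for r in kept) / len(kept)
        assert pcts[name] == pytest.approx(expected)
    assert pcts["Charged"] >= pcts["Basic"] and pcts["Charged"] >= pcts["Acidic"]
    reversed_pcts = category_percentages(s[::-1], scheme)
    for name in pcts:
        if math.isnan(pcts[name]):
            assert math.isnan(reversed_pcts[name])
        else:
            assert reversed_pcts[name] == pytest.approx(pcts[name])
    standard = [r for r in kept if r in STANDARD_RESIDUES]
    if standard:
        total = pcts["Hydrophilic"] + pcts["Neutral"] + pcts["Hydrophobic"]
        assert total == pytest.approx(100, abs=1e-6)


def test_feature_table_shape_and_labels(mixed_dataset):
    table = build_feature_table(mixed_dataset)
    assert len(table) == 4
    assert set(table["label"]) == {0, 1}
    assert "FW1_Tiny" in table.columns and "FW4_Hydrophilic" in table.columns


def test_feature_table_missing_region_is_nan():
    ds = SequenceDataset(
        [seq("a", [("1", "K")]), seq("b", [("103", "W")], domain_class="VHH")]
    )
    table = build_feature_table(ds)
    assert np.isnan(table.loc["a", "FW4_Tiny"])
    assert not np.isnan(table.loc["b", "FW4_Tiny"])


def test_aa_frequency_columns_by_hand():
    ds = SequenceDataset(
        [seq("a", [("1", "A"), ("2", "A"), ("3", "G")]),
         seq("b", [("1", "A")], domain_class="VHH")]
    )
    table = build_feature_table(ds, include_aa_freqs=True)
    assert table.loc["a", "FW1_A"] == pytest.approx(200 / 3)
    assert table.loc["a", "FW1_G"] == pytest.approx(100 / 3)


def test_residue_difference_zero_for_identical_compositions():
    ds = SequenceDataset(
        [seq("a", [("94", "R")]), seq("b", [("94", "R")], domain_class="VHH")]
    )
    diff = residue_class_difference(ds)
    assert (diff["difference"].abs() < 1e-12).all()


def test_residue_difference_clipped_to_heatmap_scale():
    ds = SequenceDataset(
        [seq("a", [("94", "R")]), seq("b", [("94", "A")], domain_class="VHH")]
    )
    diff = residue_class_difference(ds).set_index("class")
    assert diff.loc["Basic", "difference"] == -50.0  # -100 clipped


def test_positions_in_one_class_only_are_flagged_alternating():
    ds = SequenceDataset(
        [seq("a", [("94", "R")]),
         seq("b", [("94", "A"), ("95", "G")], domain_class="VHH")]
    )
    diff = residue_class_difference(ds)
    rows95 = diff[diff["position"] == "95"]
    assert rows95["alternating"].all()
    assert rows95["difference"].isna().all()


def test_difference_requires_both_classes():
    ds = SequenceDataset([seq("a", [("94", "R")])])
    with pytest.raises(ValueError):
        residue_class_difference(ds)
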