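"""Generator determinism, exact-count semantics and validity of samples."""

import numpy as np
import pytest

from vhhprof import (
    ClassConfig,
    GeneratorConfig,
    GeneratorError,
    SpeciesBlock,
    default_config,
    default_vhh_config,
    generate,
    profile_dataset,
)
from vhhprof.dataset import VALID_RESIDUES
from vhhprof.io import dumps_numbered_table
from vhhprof.metrics import region_length
from vhhprof.synthetic import config_from_dict, config_to_dict


def _small_exact_vhh(salt=(3, 2, 5), disulfide=(1, 7, 2)):
    cfg = default_vhh_config()
    cfg.species = {
        "Lama glama": SpeciesBlock(
            count=10,
            salt_bridge_mix={"canonical": salt[0], "noncanonical": salt[1], "none": salt[2]},
            disulfide_mix={
                "no_bond": disulfide[0],
                "canonical_only": disulfide[1],
                "canonical_plus_noncanonical": disulfide[2],
            },
        )
    }
    return GeneratorConfig(vhh=cfg)


def test_same_seed_is_bit_identical():
    cfg = default_config()
    a = generate(cfg, {"VH": 25, "VHH": 25}, seed=42)
    b = generate(cfg, {"VH": 25, "VHH": 25}, seed=42)
    assert dumps_numbered_table(a) == dumps_numbered_table(b)
    c = generate(cfg, {"VH": 25, "VHH": 25}, seed=43)
    assert dumps_numbered_table(c) != dumps_numbered_table(a)


def test_hcdr3_point_mass_is_exact():
    cfg = default_vhh_config()
    cfg.hcdr_length_dists["HCDR3"] = {15: 1.0}
    ds = generate(GeneratorConfig(vhh=cfg), {"VHH": 40}, seed=1)
    assert all(region_length(rec, "HCDR3") == 15 for rec in ds)


def test_exact_count_mix_recovered_with_zero_error():
    ds = generate(_small_exact_vhh(), seed=9)
    table = profile_dataset(ds)
    salt = table.salt.loc[("VHH", "Total")]
    assert (salt["canonical"], salt["noncanonical"], salt["none"]) == (3, 2, 5)
    disulfide = table.disulfide.loc[("VHH", "Total")]
    assert (disulfide["no_bond"], disulfide["canonical"], disulfide["noncanonical"]) == (1, 9, 2)


def test_exact_counts_must_sum_to_species_total():
    bad = _small_exact_vhh(salt=(3, 2, 4))  # sums to 9, total is 10
    with pytest.raises(GeneratorError, match="sum"):
        generate(bad, seed=0)


def test_proportion_mode_converges_within_three_binomial_sd():
    n = 5000
    cfg = default_config()
    ds = generate(cfg, {"VH": n, "VHH": 0}, seed=2024)
    table = profile_dataset(ds)
    observed = table.salt.loc[("VH", "Total")]
    for cls, p in cfg.vh.salt_bridge_mix.items():
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed[cls] - n * p) <= 3 * sd, cls


def test_generated_sequences_respect_core_invariants():
    ds = generate(default_config(), {"VH": 40, "VHH": 40}, seed=5)
    assert len({rec.id for rec in ds}) == len(ds)
    for rec in ds:
        positions = rec.positions()
        assert positions == sorted(positions)
        assert set(rec.residues.values()) <= VALID_RESIDUES
        assert all(1 <= p.number <= 113 for p in positions)


def test_unsatisfiable_extra_cysteine_placement_is_an_error():
    cfg = _small_exact_vhh(salt=(0, 0, 10), disulfide=(0, 0, 10))
    cfg.vhh.hcdr_length_dists["HCDR3"] = {1: 1.0}
    cfg.vhh.noncanonical_pair_dist = {"HCDR3-HCDR3": 1.0}
    with pytest.raises(GeneratorError, match="cannot host"):
        generate(cfg, seed=0)


def test_salt_bridge_class_needs_position_101():
    cfg = _small_exact_vhh(salt=(10, 0, 0), disulfide=(0, 10, 0))
    cfg.vhh.hcdr_length_dists["HCDR3"] = {1: 1.0}  # 101 never occupied
    with pytest.raises(GeneratorError, match="101"):
        generate(cfg, seed=0)


def test_config_dict_roundtrip():
    cfg = default_config(seed=7)
    back = config_from_dict(config_to_dict(cfg))
    a = generate(cfg, {"VH": 10, "VHH": 10}, seed=7)
    b = generate(back, {"VH": 10, "VHH": 10}, seed=7)
    assert dumps_numbered_table(a) == dumps_numbered_table(b)


def test_proportion_mode_requires_n():
    with pytest.raises(GeneratorError, match="n_per_class"):
        generate(default_config(), None, seed=0)
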