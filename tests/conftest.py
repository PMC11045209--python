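import pytest

from vhhprof import ChothiaPosition, NumberedSequence, SequenceDataset


def seq(sid, pairs, species="Homo sapiens", domain_class="VH"):
    """Build a NumberedSequence from (position-label, residue) pairs."""
    residues = {ChothiaPosition.from_label(lbl): res for lbl, res in pairs}
    return NumberedSequence(sid, species, domain_class, residues)


def hcdr3_seq(sid, length, domain_class="VH", species="Homo sapiens"):
    """A sequence whose HCDR3 occupies `length` positions (base + 100X)."""
    labels = [str(n) for n in range(95, 103)]
    if length <= 8:
        labels = labels[:length]
    else:
        labels = labels[:6] + [f"100{chr(ord('A') + i)}" for i in range(length - 8)] + ["101", "102"]
    return seq(sid, [(lbl, "G") for lbl in labels], species, domain_class)


@pytest.fixture
def mixed_dataset():
    """Tiny two-class dataset with controlled bridge landmarks."""
    records = [
        seq("vh1", [("22", "C"), ("92", "C"), ("94", "R"), ("101", "D"), ("103", "W")]),
        seq("vh2", [("22", "C"), ("92", "C"), ("94", "K"), ("101", "E"), ("103", "W")]),
        seq("vhh1", [("22", "C"), ("92", "C"), ("94", "A"), ("101", "S"), ("103", "W")],
            species="Lama glama", domain_class="VHH"),
        seq("vhh2", [("22", "S"), ("92", "A"), ("94", "A"), ("103", "W")],
            species="Lama glama", domain_class="VHH"),
    ]
    return SequenceDataset(records)
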