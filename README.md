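# vhhprof

Comparative sequence profiling of conventional antibody heavy-chain variable
domains (VH) and camelid single-domain antibody variable domains (VHH,
"nanobodies").

Camelids produce heavy-chain-only IgGs whose variable domain works without a
light-chain partner. Relative to VH domains, VHHs carry longer HCDR3 loops, a
hydrophilic hallmark motif at the former VH–VL interface (Chothia positions
37/44/45/47: VGLW in VH becomes FERF/YERF in VHH), extra "noncanonical"
disulfide bridges beyond the conserved 22C–92C pair, and they largely lack the
salt bridge between a basic residue at position 94 and an acidic residue at
position 101 that flanks HCDR3 in VHs. These differences drive nanobody
engineering (camelization/humanization), and `vhhprof` quantifies them from
Chothia-numbered sequences:

- **Region segmentation** over the Chothia windows FW1 1–25, HCDR1 26–32,
  FW2 33–51, HCDR2 52–56, FW3 57–94, HCDR3 95–102, FW4 103–113 (insertion
  letters such as 100A belong to the window of their base number).
- **HCDR length profiling**: per-region lengths, length-frequency
  distributions and per-(class, species) summary tables.
- **Motif conservation**: position-frequency matrices with per-column
  information content `bits = log2(20) − H(p)` and consensus/hallmark motifs.
- **Bridge rules**: canonical disulfide = C at 22 and 92; extra cysteines are
  paired greedily in sequence order and labelled by region pair
  (e.g. HCDR1–HCDR3). Salt-bridge rule at (94, 101): canonical = R–D;
  noncanonical = {R,K,H} × {D,E} minus R–D; otherwise none.
- **Physicochemical featurization**: per-region percentages of the
  overlapping Pepstats property classes (Tiny, Small, Aliphatic, Aromatic,
  Non-polar, Polar, Charged, Basic, Acidic) and the hydropathy partition
  (Hydrophilic/Neutral/Hydrophobic).
- **Feature selection** for the binary classification VH = 0 vs VHH = 1 with
  the logistic model `ln(p/(1−p)) = β0 + β1 x1 + … + βk xk`: variance
  inflation factor filtering (drop while any VIF = 1/(1−R²) > 10), backward
  stepwise elimination by likelihood-ratio test, McFadden pseudo-R²
  (1 − ll/ll_null), rank-based AUC, odds ratios Exp(β) with 95% CIs
  (Exp(β) > 1 marks VHH-enriched features), and a Boruta shadow-feature
  selector around a random forest.
- **Synthetic repertoire generator** with an exact-count mode: trait mixes
  given as integer counts per species are reproduced deterministically, so
  the bundled reference composition of a 5030-sequence VH survey and a
  1260-sequence VHH survey (abYsis / sdAb-DB style) can be regenerated and
  re-derived by the classifiers with zero error.

## Worked example

```python
import vhhprof as v

ds = v.generate(v.reference_config(), seed=1)   # 6290 sequences
table = v.profile_dataset(ds)
print(table.salt_percentages().loc[[("VH", "Total"), ("VHH", "Total")]])
print(table.disulfide_percentages().loc[[("VH", "Total"), ("VHH", "Total")]])
```

prints

```
               canonical  noncanonical  none  total
class species
VH    Total         56.3           6.8  36.9   5030
VHH   Total          1.5           1.3  97.2   1260

               no_bond  canonical  noncanonical  total
class species
VH    Total        0.1       99.9           2.6   5030
VHH   Total        0.1       99.9           5.5   1260
```

Reading: 56.3% of VHs carry the canonical R94–D101 salt bridge and 63.1%
carry some 94/101 salt bridge, while 97.2% of VHHs have none; 2.6% of VHs but
5.5% of VHHs carry a noncanonical disulfide pair in addition to the canonical
22C–92C bond. Consensus hallmark motifs at 37/44/45/47 come out as `VGLW`
(VH) and `FERF` (VHH):

```python
from vhhprof import ChothiaPosition as P
from vhhprof.motifs import frequency_matrix, motif_at
motif_at(frequency_matrix(ds, "VH"), [P(37), P(44), P(45), P(47)])   # 'VGLW'
motif_at(frequency_matrix(ds, "VHH"), [P(37), P(44), P(45), P(47)])  # 'FERF'
```

The same analyses run from the shell:

```bash
vhhprof generate --reference --seed 1 --out repertoire.tsv
vhhprof bridges repertoire.tsv --out-dir out/
vhhprof features repertoire.tsv --out features.csv
vhhprof model features.csv --mode collective
vhhprof run-all --seed 1 --out-dir run/
```

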