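# Methods

## Scope and data model

`vhhprof` analyses Chothia-numbered heavy-chain variable-domain amino-acid
sequences carrying a species label and a domain-class label (VH or VHH). It
does **not** perform numbering or alignment: inputs are pre-numbered (ANARCI
or equivalent produces such tables), stored as maps from Chothia positions to
residues. Unresolved residues are absent positions, never gap characters.
Positions are totally ordered, `(n) < (n,A) < … < (n+1)`; insertion letters
are accepted at any base position 1–113 (observed ranges in real repertoires
include 31A–G, 52A–I and 100A–B), while the region windows stay strict:
FW1 1–25, HCDR1 26–32, FW2 33–51, HCDR2 52–56, FW3 57–94, HCDR3 95–102,
FW4 103–113, tiling 1–113 without gap or overlap. Residue codes are the 20
standard letters plus B, Z (classified by the property scheme) and X
(accepted, excluded from all compositional counts).

## Synthetic repertoire generator

The generator emulates the statistical structure the downstream analyses
assume, per domain class:

- **Species composition** — exact integer counts per species or weights
  apportioned by largest remainder. The bundled reference composition mirrors
  a curated 5030-sequence mammalian VH survey (eight species/chimera groups,
  abYsis-style) and a 1260-sequence camelid VHH survey (five groups,
  sdAb-DB-style), including their per-species disulfide and salt-bridge
  count tables.
- **Framework scaffold** — per-region consensus strings (germline-like VH3
  backbone for VH; a camelid-like variant for VHH, starting Q1, Q108);
  each non-landmark position keeps its consensus residue with probability
  0.8, otherwise substitutes uniformly over the 18 alternatives excluding
  cysteine. Excluding C from noise is what makes exact-count disulfide
  tables exact; it is the one deliberate distortion of the background model.
- **Hallmark motif** — positions 37/44/45/47 are drawn per sequence from a
  motif mixture (VH: VGLW; VHH: 0.6 FERF / 0.4 YERF) and kept with
  probability 0.95.
- **HCDR loops** — lengths drawn from per-region categorical distributions
  (defaults: HCDR1 mode 7, HCDR2 mode 6, HCDR3 mode 10 for VH and 15 for
  VHH, with unimodal tails). Loops shorter than the base window vacate the
  middle (filled from both ends), as Chothia deletions do; longer loops add
  insertion letters at the anchors 31/52/100. Loop residues are drawn i.i.d.
  from a CDR-like residue pool without cysteine.
- **Salt-bridge mix** over {canonical, noncanonical, none} controls residues
  at 94/101: canonical sets R/D; noncanonical draws uniformly from the five
  remaining basic×acidic combinations; "none" draws 94 from {A,G,S,T,V}
  (alanine weighted 0.6 so that the VHH consensus at 94 is A, matching
  camelid repertoires) and 101 from {G,S,T,N,Q}, guaranteeing
  rule-negativity.
- **Disulfide mix** over {no_bond, canonical_only, canonical_plus_noncanonical}:
  the canonical classes set C at 22 and 92; the noncanonical class
  additionally converts to cysteine the two lowest-numbered non-landmark
  positions of a region pair drawn from a configurable distribution
  (VH vocabulary: HCDR1–HCDR2, HCDR1–HCDR3, FW2–HCDR2, HCDR3–HCDR3;
  VHH: HCDR1–HCDR3, FW2–HCDR3, HCDR3–HCDR3). A pair that cannot be hosted
  (e.g. a one-residue HCDR3 for HCDR3–HCDR3) is a hard error.

Mixes whose values are all integers are **exact counts**: label lists are
materialized and shuffled, so downstream classifiers recover the configured
counts with zero error, not in expectation. Randomness is split per sequence
from the master seed via `SeedSequence(seed, spawn_key=(class, crc32(species),
index))`, so inserting a record never reshuffles others and the same
(config, seed) is bit-identical.

What the generator does **not** emulate: germline V(D)J usage, somatic
hypermutation, positional covariance, realistic per-species framework
differences beyond the consensus strings, or residue composition of real
CDRs. Passing tests therefore demonstrate correctness of the measurement and
classification machinery under controlled conditions, not biological fidelity
of the sequences themselves.

## Length, motif and bridge analyses

Region length counts occupied positions (base + insertions) in the window;
empty regions count as 0 and are reported via a missingness column rather
than dropped. Mode ties report the smallest modal length, with all tied modes
retained in metadata. Sequence-weighted means are reported to one decimal.

Logo matrices compute per-column residue frequencies over occupying
sequences only, with occupancy (fraction of sequences occupying the column)
reported separately and X excluded from frequencies but counted in
occupancy. Information content is `log2(20) − H` in bits with no small-sample
correction, clamped at 0 (relevant only if B/Z inflate a column's support
beyond 20 symbols); an occupancy-weighted `bits × occupancy` column is
exported for stack-height-style rendering. Consensus ties break
alphabetically and are flagged.

The disulfide profiler treats the 22/92 cysteine pair as canonical and pairs
any extra cysteines greedily in ascending position order; region-pair labels
are normalized lower-position-first. This sequence-level pairing is a
documented stand-in for structural bond confirmation (which requires 3D
models and is out of scope), so pair categories are putative. In the
aggregated tables "noncanonical" counts sequences that also carry the
canonical bond — a subset of the canonical column — while
no_bond + canonical = total; the salt-bridge triple is a true partition.
Percentages round half-up to the printed precision; note that summary tables
derived from such counts elsewhere sometimes truncate instead (35/1260 =
2.78% may appear as 2.7%), which this package does not imitate.

The salt-bridge rule is sequence-level only: histidine counts as basic, and
an absent 94 or 101 yields "none". The structural 4.0 Å side-chain distance
criterion used to verify salt bridges in 3D is documented here but not
computed.

## Featurization and models

Per-region percentages use the Pepstats property sets (Tiny ACGST; Small
ABCDGNPSTV; Aliphatic AILV; Aromatic FHWY; Non-polar ACFGILMPVWY; Polar
DEHKNQRSTZ; Charged BDEHKRZ; Basic HKR; Acidic BDEZ) and the hydropathy
partition (Hydrophilic DEKNRQ; Neutral GHPTSY; Hydrophobic ACFILMVW).
Classes overlap by design. X is excluded from numerator and denominator; B/Z
count in the property classes but not in hydropathy, whose denominator is
restricted to the 20 standard residues. Empty or all-X regions propagate as
missing cells; modelling drops incomplete rows with a logged count. Feature
names follow `<region>_<Class>` (e.g. `FW2_Hydrophilic`); by default only
FW1–FW4 are featurized, because CDR hypervariability confounds class
comparisons. The per-residue difference map reports, for each position and
class, the VHH-minus-VH membership percentage difference clipped to ±50 for
heatmap export, with single-class positions flagged "alternating".

The logistic model is fitted by Newton/IRLS via statsmodels (convergence
tol 1e-8, 100 iterations); complete separation is detected, flagged, and the
fit is rerun with BFGS so coefficients remain reportable with a warning that
standard errors are unreliable. VIF filtering removes the single worst
predictor with VIF > 10 and recomputes until all pass; ties break to the
lexicographically later column; constant columns carry infinite VIF and go
first. Backward elimination drops, per step, the feature whose removal has
the largest likelihood-ratio p-value above α = 0.05 (χ², df 1). The pipeline
order is VIF first, then stepwise. "Variable importance" is the absolute
Wald z-statistic of each term — a standard, model-intrinsic choice,
swappable. Confidence intervals are 95% on the odds-ratio scale; AIC is
reported informationally. AUC is the rank-based Mann–Whitney statistic (ties
contribute ½).

The Boruta selector appends a shuffled shadow copy of every feature each
iteration, fits a random forest (defaults: 100 iterations, 500 trees, both
configurable), and scores features by mean decrease in accuracy under
permutation. Permutation importance is computed **in-sample** on the fitted
forest (scikit-learn's `permutation_importance`); out-of-bag permutation
importance would require private forest internals, and impurity importance is
available as a faster option. Hits (feature importance above the iteration's
maximum shadow importance) are tested against Bin(n, ½) one-sided in both
directions with Holm step-down at α = 0.05; tentative features stay
tentative. Fewer than five completed iterations leaves everything tentative
with a warning. Seeded runs are bit-reproducible.

## Problem sizes and numerical choices

The test suite and acceptance script use: the full exact-count reference
composition (6290 sequences) for the bridge-rate recomputations; n = 2000 per
class for HCDR3 mode checks; n = 5000 × 100 replicates for logistic CI
coverage of planted coefficients (1.5, −0.8); and n = 500 with 20 iterations
× 80 trees × 20 seeded runs for the Boruta planted-signal check — sizes
chosen so each stage establishes its property with comfortable statistical
margin at modest cost. Tolerances: exact equality for count recovery and the
salt-bridge rule oracle; 1e-12 for information content vs the entropy
formula; 1e-8 for VIF vs its least-squares definition; exact (1e-12) for AUC
vs all-pairs concordance.

## Known limitations

- Fitted coefficients on real repertoires are not reproducible here: the
  underlying curated datasets are not redistributable, so the model stack is
  validated on synthetic data (layout, metric definitions, parameter
  recovery), not against published coefficient tables.
- Species-level summary rows derived from unweighted per-species averages
  elsewhere may disagree with this package's sequence-weighted means; the
  aggregate is always recomputable from the reported histograms.
- Greedy cysteine pairing can mislabel genuinely crossed bonds (1–3/2–4
  topologies); only structural analysis could resolve those.
- The generator's exact-count guarantee relies on cysteine-free background
  noise; real repertoires contain rare unpaired or oddly placed cysteines,
  which the classifiers handle (unpaired flag) but the defaults do not
  produce.
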