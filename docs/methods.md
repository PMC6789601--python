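# Methods

## Model

The score is a histogram-based outlier score: for each of the 18 scoreable
residue types (all standard amino acids except GLY and ALA, which lack χ₁)
and each of five features — φ, ψ, χ₁, side-chain size `d_sidechain`, block
length `d_block` — a histogram is accumulated over a reference corpus and
rescaled by its highest bin (a *peak-normalized density*, npdf). A residue's
score is the sum over its five features of log₁₀(1/npdf), with a fixed
penalty replacing the logarithm in effectively unobserved bins. The model is
a Naive-Bayes-style composition: features are treated as independent, and no
environmental terms (neighbors, map fit) enter. It presumes the reference
corpus contains overwhelmingly correct conformations, so low reference
density is evidence of abnormality rather than of rarity-but-validity.

## Feature definitions and conventions

- Torsions are mapped from the signed (−180, 180] convention to [0, 360) by
  adding 360 to negatives; exactly 360 wraps to 0. All histograms and
  thresholds use this scale.
- χ₁ is N–CA–CB–γ with γ = CG (CG1 for ILE/VAL, OG for SER, OG1 for THR,
  SG for CYS), configurable through the distal-block table.
- `d_sidechain` is the distance from CA to the mass-weighted centroid of all
  heavy side-chain atoms (CB included, hydrogens excluded — deposited models
  typically lack them). "Mass centroid" is read literally: weights are
  standard atomic masses. The value is treated as missing when any expected
  heavy side-chain atom of that residue type is absent, so partial side
  chains are never scored on truncated geometry.
- `d_block` is the distance from CA to the mass centroid of the side chain's
  distal rigid group. The group memberships ship as data
  (`src/hbosval/data/distal_blocks.tsv`): the terminal chemical group of each
  side chain (glutamate carboxylate CD/OE1/OE2, leucine isopropyl
  CG/CD1/CD2, full aromatic rings for PHE/TYR/TRP/HIS, CE/NZ for LYS,
  guanidinium for ARG, and the whole short side chain for SER/CYS/THR/VAL).
  The table is a documented, editable stand-in for the rigid-block
  decomposition used in prior block-based work; analyses sensitive to the
  exact membership should review it before building a database.
- Chain breaks: a torsion spanning two residues is computed only when the
  peptide bond is intact, C(i−1)–N(i) ≤ 2.0 Å. A residue-numbering gap with
  an intact bond distance is treated as a numbering artifact, not a break;
  a physical gap fails the distance test regardless of numbering.
- Alternate locations: the highest-occupancy conformer per atom name is
  kept, ties resolved by file order. Nonstandard residues (MSE, ...) are
  parsed but never scored or auto-mapped; only the 20 standard types enter
  feature extraction, and GLY/ALA are excluded from its output entirely.
- Non-crystallographic symmetry: within each structure, chains are scanned
  in file order and dropped when their global sequence identity to any
  previously kept chain is ≥ 0.95. Identity is Needleman–Wunsch (match 1,
  mismatch 0, small affine gap penalty) with identity = identical
  positions / alignment length; alignment length (not shorter-sequence
  length) is the denominator, configurable via the threshold parameter.

## Histograms

Angles use 5° bins over [0, 360) (72 bins); distances use 0.05 Å bins from
0 to a 10 Å cap (200 bins), which covers the longest side chains with
margin — typical block lengths sit below 4.5 Å. Bins are half-open
[lo, hi); 360° wraps to bin 0; a distance at or beyond the cap reads as
density 0 and therefore draws the floor penalty. Counts are raw (no
smoothing or pseudocounts); peak normalization makes the tables invariant
to corpus size. The database serializes to a single schema-versioned JSON
document (90 tables, bin specs, full-precision densities, provenance
metadata); loading verifies the version and completeness.

## Scoring parameters

| parameter | default | meaning |
|---|---|---|
| `log_base` | 10 | base of the component logarithm |
| `npdf_floor` | 0.001 | density below which the floor penalty applies (strict <; exactly 0.001 scores log₁₀1000 = 3) |
| `floor_score` | 5 | component value in a sub-floor bin |
| `flag_threshold` | 2 | per-feature "highly unfavorable" mark (density < 1% of peak) |
| `outlier_threshold` | 10 | total above which (strictly) a residue is labeled |

Base 10 is the deliberate reading of the unqualified logarithm: it makes the
flag threshold 2 correspond exactly to 1% of peak density and keeps the
floor (5) strictly above log₁₀(1/0.001) = 3, so the floor is a discontinuous
extra penalty for effectively-unobserved bins rather than a discount. The
base is a parameter; constructing parameters with a floor below
log(1/npdf_floor) is rejected. Components are therefore bounded by [0, 5]
and totals by [0, 25]. A residue missing any feature is reported unscored:
the five-term sum is not defined on a subset, and partial sums would make
termini look systematically safer.

## Synthetic data

The peptide builder places every atom by natural-extension reference frame
(NeRF) from a bond length, bond angle and torsion relative to three placed
atoms, so requested φ/ψ/ω/χ₁ are honored exactly (round-trip error is at
floating-point level, far below the 1e-4° test tolerance). Bond lengths and
angles are textbook idealized values; side chains beyond the γ atom use
fixed template torsions (extended chains, planar rings). The chains are
geometric test objects: no clash avoidance, no proline ring closure, no
crystallographic realism. Coordinates can be jittered with seeded Gaussian
noise to emulate coordinate uncertainty.

The planted-outlier corpus draws reference chains (200 peptides of length
10, random scoreable sequences) from tight unimodal torsion distributions
(φ ~ 300°, ψ ~ 320°, χ₁ ~ 300°, sd 8°, wrapped; 0.01 Å coordinate jitter)
and rebuilds 20 interior probe residues at torsions (120°, 80°, 180°) that
the reference never visits, so each violated torsion draws the floor
penalty and a planted residue totals at least 15. These sizes keep the
whole study under a few seconds while leaving ≥ 400 normal probe residues
for the false-label rate.

What passing on this corpus shows — and does not show: it validates the
pipeline's arithmetic, bin handling, floor/threshold semantics and recall
on unambiguous anomalies. Real reference corpora are multimodal (rotamer
states), contain correlated features, missing atoms and NCS, and their
"outliers" are far less separated than planted ones; recall and false-label
rates measured here do not transfer to deposited structures. Distance
features in particular are nearly constant under the builder's idealized
geometry, so their discriminative power is exercised only through the cap
and floor paths, not through realistic variation.

## Numerical choices

- Dihedrals use the atan2 cross-product construction; collinear or
  coincident triples raise a degenerate-geometry error naming the points.
  The signed torsion is invariant under full reversal of the four points, a
  property the test suite checks against random geometry.
- Peak normalization ties: two equal modes both carry density 1.
- The self-scoring calibration (scoring the reference corpus against its own
  database) can never draw a floor penalty on an accumulated value — its own
  bin holds at least one count — which is why its score tail is structurally
  short; the test threshold (< 1% above 9.5) mirrors the near-empty tail of
  a trusted corpus's score distribution.

## Limitations

- The distal-block table is a documented default, not a canonical import;
  block-length values depend on it.
- Only χ₁ among side-chain torsions is modeled; χ₂+ anomalies surface only
  through the two distance features.
- No map-to-model fit, B-factor, or neighbor context; the score flags
  geometric atypicality, not density disagreement.
- Per-feature histograms ignore feature correlations (e.g. φ/ψ coupling);
  the sum treats features as independent.
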