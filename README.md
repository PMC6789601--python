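# hbosval

Unsupervised validation of protein residue conformations with a
histogram-based outlier score (HBOS), aimed at models built into cryo-EM
density maps, where deposition-time checks (Ramachandran, rotamer, clash)
can miss geometrically abnormal side chains.

## The model

Each residue is described by five geometric features:

- **φ, ψ** — backbone torsions C(i−1)–N–CA–C and N–CA–C–N(i+1),
- **χ₁** — first side-chain torsion N–CA–CB–γ (undefined for GLY/ALA, so 18
  of the 20 standard residue types are scoreable),
- **d_sidechain** — distance from CA to the mass centroid of all heavy
  side-chain atoms ("side-chain size"),
- **d_block** — distance from CA to the mass centroid of the side chain's
  distal rigid group, e.g. the glutamate carboxylate or the leucine
  isopropyl ("block length").

Torsions are reported on a 0–360° scale. From a trusted reference corpus,
each (residue type, feature) pair gets a histogram (5° bins for angles,
0.05 Å bins for distances; 18 × 5 = 90 tables) rescaled by its highest bin —
a *peak-normalized density* (npdf). A residue with feature values
v₁…v₅ scores

```
HBOS = Σᵢ log₁₀( 1 / npdfᵢ(vᵢ) )
```

with a floor rule: a bin whose density is below 0.001 contributes a fixed
penalty of 5 instead of a divergent logarithm. A residue is labeled an
**outlier** when its total exceeds 10 (strictly); an individual feature
score above 2 (density < 1% of the peak) marks that feature as highly
unfavorable. Residues with any missing feature (chain termini, breaks,
incomplete side chains) are reported as unscored, never silently labeled.

The package also ships a synthetic peptide builder (exact internal-coordinate
placement of requested φ/ψ/ω/χ₁) so the whole pipeline is testable without
downloading structures.

## Worked example

Build a reference database from a synthetic corpus and score a probe chain
carrying two residues deliberately built at conformations the reference
never visits:

```
$ hbosval build-ref --in ref/ --out db.json
$ hbosval score --in probe.pdb --db db.json --chain A --mode outliers
Residue Index   B-Dist  S-Dist  Phi     Psi     Chi_1   Total   Outlier Flagged
ASN     4       0.00    0.00    5.00    5.00    5.00    15.00   True    Phi,Psi,Chi_1
TRP     5       1.13    0.00    5.00    5.00    5.00    16.13   True    Phi,Psi,Chi_1
```

Both planted residues hit the floor penalty on all three torsions
(3 × 5 = 15 > 10) and are the only labeled outliers; `--mode full` lists
every scored residue (ordinary ones total well under 1 here). Columns follow
the validation-report convention: `B-Dist`/`S-Dist` are the block-length and
side-chain-size scores, then the three torsion scores and the total.
`--chimera-attr out.attr` additionally writes a residue-attribute file for
coloring a structure by score in a viewer, and `--format json` gives the
same rows at full precision.

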