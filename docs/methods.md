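# Methods

## Problem and scope

`structvalid` quantifies how well predicted protein models (AlphaFold-style,
with per-residue pLDDT in the B-factor column and a predicted-aligned-error
matrix) agree with ensembles of crystal structures of the same protein. The
guiding question is whether a predicted model is an *outlier* relative to
the spread already present among crystal structures solved under different
conditions, or whether it falls inside that spread. The toolkit also covers
two satellite analyses used in the same kind of study: buried
solvent-accessible surface area between two residue groups, and enrichment
of a PROSITE-style sequence motif in a protein list.

## Structural dissimilarity

**RMSD.** Classical root-mean-square deviation after optimal rigid
superposition, computed with the closed-form Kabsch solution (SVD of the
covariance matrix, reflection corrected to keep det R = +1). Three atom
levels are supported: `calpha` (Cα only), `mainchain` (N, CA, C, O), and
`allatom` (heavy atoms shared by name between the paired residues —
hydrogens are absent from most crystal models, and comparing name-shared
atoms sidesteps point mutations in engineered constructs, which are
reported but not excluded). Collinear point sets warn instead of failing:
the minimizing rotation is then non-unique but the minimum RMSD is still
well defined, and tiny test fixtures are legitimate inputs.

**IRDM metric.** The inter-residue distance map of a structure is the n×n
matrix of Cα–Cα Euclidean distances. Given two structures on a shared
residue correspondence, each residue contributes a row discrepancy
e_i = √Σ_j (d1_ij − d2_ij)², and the overall metric is
√((1/n) Σ_i e_i²) = ‖D1 − D2‖_F / √n. The "root mean of the squared
row differences" and the "RMS of the per-residue Euclidean distances"
readings are the same number; the package implements the single Frobenius
definition and property-tests the identity. Being built on internal
distances the metric is translation/rotation invariant (no superposition)
— and chirality-blind: a structure and its mirror image have IRDM distance
zero but positive RMSD. A dedicated test documents this.

**Correspondence.** Predicted models are full-length while crystal models
have gaps, so all pairwise work runs through an explicit residue map built
on author numbering (chain, seqnum, insertion code), optionally with a
chain renaming. Sequence-alignment-based matching is deliberately out of
scope: the target use case (UniProt-numbered predicted models vs
PDB-deposited structures of the same protein) shares numbering. Residues
lacking the atoms a level demands are dropped from the map.

## Ensemble analysis

Pairwise dissimilarity matrices (either metric) are computed by default on
the *ensemble-wide* common residue set, so every entry shares one n and the
matrix is coherent for clustering; a pairwise-common mode exists for
two-structure work. Clustering is standard agglomerative linkage (scipy);
the default is average linkage (UPGMA) since none is canonical for this
task, with complete and single available. The outlier test cuts the
dendrogram at a stated height and asks whether the predicted model sits
alone in its cluster; cutting at 0 trivially isolates every leaf, so the
height is part of the claim, in the units of the metric (Å).

Group statistics compare predicted-vs-crystal values (m entries for m
crystal structures) against crystal-vs-crystal values (the m(m−1)/2 upper
triangle) with Welch's unequal-variance t-test. The resolution–deviation
analysis correlates crystal resolution with RMSD to a chosen reference
(excluded from the pairs) using Pearson's r with the t-statistic p-value.

## Confidence-score statistics

pLDDT (read from the B-factor column of predicted models, validated to
[0, 100]) is related to crystallographic B-factors by Spearman rank
correlation — the relation is monotone, not linear. The PAE matrix is
reduced to one value per residue before correlating with B-factors; the
default reduction is the row mean (expected error of residue i averaged
over alignment frames), with column-mean and symmetric-mean options since
the choice is genuinely open. Confidence categories use the thresholds
high ≥ 98.5, 96.0 ≤ medium < 98.5, low < 96.0. All p-values in the package
are two-sided.

## SASA

Shrake–Rupley with a deterministic golden-spiral point set (no RNG), probe
radius 1.4 Å, 960 points per atom by default, and an element-keyed van der
Waals radius table (C 1.70, N 1.55, O 1.52, S 1.80 Å, …); unknown elements
raise by name rather than guessing. Convergence is better than 0.5%
between 960 and 7680 points on helical test bodies. Buried interface area
between residue groups A and B is SASA(A) + SASA(B) − SASA(A∪B) with all
other atoms excluded (the two groups as an isolated complex), matching the
usual interface-burial definition; a `context=True` mode keeps the rest of
the structure present in all terms and subtracts the isolated rest, which
cancels the group–context burials. Interface residue ranges are always
user input — never inferred from geometry.

## Motif enrichment

The PROSITE scanner supports letters, `x`, `[..]`, `{..}`, `(n)`/`(n,m)`
repetitions and `<`/`>` anchors, compiled to a lookahead regex so each
start position is tested independently and overlapping occurrences are all
counted (a brute-force window checker is the property-test oracle). Fold
enrichment is (hits/protein) / (background matches/background sequence),
with the published background of 10,318 expected matches per 100,000
sequences as the default for the P-x-L-x-P motif. The background figure is
treated as a *match count* (not sequences-with-a-match); the two readings
are close for rare motifs but the choice is explicit. No per-motif test is
canonical here, so significance uses a Poisson count test with
λ = n_proteins × background_rate, and Benjamini–Hochberg FDR across motifs
when several are tested.

## Synthetic ensembles

The generator emulates the variability among crystal structures of one
protein solved in different lattices: a base Cα trace (ideal α-helix —
rise 1.5 Å, 100°/residue, radius 2.3 Å — random coil, or both) perturbed
per member by iid Gaussian coordinate noise with per-residue σ_i, then an
optional random rigid motion. Under this model E[deviation²] = 3σ² per
residue, so member-vs-base RMSD concentrates at √3·σ and member-vs-member
at √(3(σ_i²+σ_j²)); these closed forms anchor the recovery tests. Members
carry B-factors via the isotropic displacement relation B = 8π²σ², and the
base carries a pLDDT-like track 100 − 40σ/(σ_max+ε) clipped to [50, 100] —
any monotone-decreasing map suffices for the sign-recovery tests. Planted
group structure is injected as a sinusoidal chain bend of differing
amplitude (a conformational change), because a plain translation offset
would be removed by superposition and by the IRDM's invariance alike.

Default study conditions used in tests and the acceptance script: 300
residues at σ = 0.5 Å for the √3σ recovery (10% tolerance), 150 residues ×
6 members with bend amplitudes {0, 15 Å} for planted-partition recovery,
and 150 residues with σ ~ |N(0.3, 0.15²)|+0.02 for the confidence-score
sign tests. What the generator does *not* emulate: real backbone geometry
(φ/ψ), correlated domain motions, crystal-contact-induced local
deformations, and anisotropic B-factors — so passing tests demonstrate
metric correctness and statistical power under the stated noise model, not
performance on real lattice artifacts.

## Numerical choices and limitations

- PDB coordinates round-trip at 3 decimals; equality tests on files use
  1.5e-3 Å tolerances.
- Altloc policy: highest occupancy wins, ties to the first encountered.
  Hydrogens, waters and hetero residues are dropped unconditionally.
- Dissimilarity matrices are symmetrized exactly by construction; linkage
  tie-breaking follows scipy's deterministic ordering of the condensed
  matrix, so a fixed input order yields a fixed tree.
- Reproducing published ensemble statistics for real proteins requires the
  corresponding PDB/AlphaFold-DB coordinate files as inputs; the package
  deliberately ships no download client, and all shipped validation runs on
  generated data.
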