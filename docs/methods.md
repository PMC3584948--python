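# Methods

## Target function

Local model correctness is the S-score `S_i = 1 / (1 + (d_i/d0)^2)` with
`d0 = 3 Å`, where `d_i` is the Cα deviation of residue *i* under the rigid
superposition that maximizes `Σ S_i` over the whole model.  The inverse view
`d = d0·sqrt(1/S − 1)` converts predictions back to distances for output.
The maximizing superposition is found MaxSub-style: every contiguous
7-residue window seeds a least-squares (Kabsch) fit; residues within an
inclusion threshold are iteratively re-added and the fit repeated until the
inlier set is stable (at most 10 iterations).  Seeds are extended at three
inclusion thresholds (1, 2 and 3.5 × d0) — tight thresholds lock onto
well-modeled cores, the wide one tolerates moderate global error — and an
all-residue Kabsch fit is always among the candidates, so the search never
scores below a plain superposition.  Unmodeled target residues carry S = 0
and undefined distance.  GDT_TS uses the same seed-and-extend heuristic per
threshold (1, 2, 4, 8 Å) and reports the mean maximal fraction × 100; this
is the standard heuristic approximation, not the exhaustive LGA search.
Fewer than 7 matched residues fall back to the all-residue fit.

## Features

Each residue is described by a 160-component vector; histograms are
normalized within the window and windows truncated at the termini divide
by the actual residue count, never the nominal window length.

| block | size | definition |
|---|---|---|
| atom contacts | 91 | 13×13 upper triangle; contact = heavy-atom pair ≤ 4 Å, pairs with sequence separation ≤ 1 excluded; counted when either atom's residue is inside the 21-window, partner may lie outside; normalized by window total |
| residue contacts | 21 | 6×6 upper triangle; contact = any {Cα, side-chain} atom pair ≤ 6 Å with separation > 5; profile-weighted; normalized by window total |
| exposure | 24 | 6 groups × 4 burial bins ([0,25], (25,50], (50,75], (75,100] %; boundary values to the lower bin); profile-weighted; normalized by window residue count |
| predicted SS at center | 3 | three-state probabilities (H, E, C) |
| SS agreement (21-window) | 1 | fraction where predicted class equals assigned class |
| assigned SS (5-window) | 15 | one-hot over H/E/C, absent positions zero |
| burial agreement (21-window) | 1 | exposed iff relative side-chain area ≥ 25 % |
| mean exposure (13-window) | 1 | mean relative side-chain area |
| conservation (3-window) | 1 | mean information-per-position from the profile |
| global agreements | 2 | the SS and burial agreements averaged over the whole model — identical for every residue of one model |

The 13 atom classes partition heavy atoms by chemical character (backbone
N/Cα/C/O, Cβ, aliphatic C, aromatic C, polar sp² side-chain C, side-chain
amine/amide/guanidinium N, ring N, hydroxyl O, carboxylate/amide O, S); the
table in `structure_io.py` is the single source of truth.  The 6 residue
groups are (1) R K, (2) D E, (3) H F W Y, (4) N Q S T, (5) A I L M V C,
(6) G P.

**Profile weighting.**  A residue whose profile position holds 40 % alanine
and 60 % serine contributes 0.4 to group 5 and 0.6 to group 4 wherever its
identity enters the residue-contact or exposure histograms.  Weighting is
linear: a mixed profile's features equal the frequency-weighted average of
pure-residue features (asserted as a property test).

**The base window** for the contact/exposure histograms is 21 residues.
Only the agreement-feature window lengths (21/13/5/3) are fixed by the
method description; the base window is a configurable default chosen to
match them.

## Secondary structure and surface area

Secondary structure is assigned internally from backbone φ/ψ dihedrals
(helix region −100 ≤ φ ≤ −30, −80 ≤ ψ ≤ −4; strand region φ ≤ −45 with
ψ ≥ 90 or ≤ −150; runs shorter than 4 (helix) / 3 (strand) decay to coil;
termini are coil).  Readers for STRIDE and DSSP output files are provided
for users who prefer an external assignment; codes map {H,G,I}→H, {E,B}→E,
else C.

SASA is Shrake–Rupley with probe 1.4 Å and 960 quasi-uniform sphere points
per atom (golden-spiral layout).  Van der Waals radii: C 1.70, N 1.55,
O 1.52, S 1.80 Å.  Relative side-chain exposure divides side-chain SASA by
the Miller Gly-X-Gly maximum side-chain area, capped by the isolated-sphere
area of the atoms actually present so that models with placeholder side
chains (Cβ only) still saturate at 1 when unoccluded; glycine uses its
backbone-inclusive total area.  Doubling the point count changes per-atom
areas by well under 2 % (convergence test), and per-atom areas agree with
an independent Shrake–Rupley implementation on identical radii.

## Regressor

A linear ε-insensitive SVR maps standardized features to S-scores.
Hyperparameters are grid-searched over C ∈ {0.01, 0.1, 1, 10} and
ε ∈ {0.05, 0.1, 0.2}, scored by mean held-out Pearson R over 5
cross-validation folds that split **by target** — residues of one target
never straddle a fold boundary, since models of one target are strongly
correlated.  One (C, ε) pair is chosen globally, and the final model is
refit on all rows.  When the training table exceeds 4 000 rows the grid
search runs on a seeded random row subsample (folds still split by target);
the final refit always uses the full table.  Raw predictions are clamped to
[0, 1]; the global score is `Σ S_i / target_length`.  Models serialize to
versioned JSON carrying a feature-layout fingerprint; prediction refuses a
mismatched layout.

## Consensus

The consensus score of model *m* at residue *r* is the mean, over the other
ensemble members, of the S-score similarity at *r* under the pairwise
optimal superposition — the standard average-pairwise-similarity consensus
construction, using the same machinery as the target function.  The hybrid
score is `(1−k)·S_single + k·S_consensus`, k = 0.8 by default and exposed
as a flag.

## Synthetic data generator

`fixtures` emulates a CASP-style target: an ideal-geometry native (helix,
extended strand, seeded random-torsion coil, or two helical domains with an
extended linker; backbone built by NeRF from internal coordinates, side
chains reduced to Cβ placeholders), a ladder of perturbed models, and
sequence-derived predictions of configurable accuracy (default 0.85, with
disagreements uniform over the remaining classes; profile = one-hot
sequence blended with uniform at rate 0.3).  Perturbations are per-residue
Gaussian displacement fields smoothed along the chain (window 5, rescaled
to scale σ) so errors are locally correlated as in real models; the default
σ ladder 0.25–9 Å spans near-native to essentially random.  True local
quality is computed with the same superposition code used for scoring and
is self-consistency-tested.

What the generator does **not** emulate: real side-chain packing and
rotamers, physically plausible decoy energetics, alignment-derived profile
statistics, correlated prediction errors, multi-chain or gapped models.
Passing tests therefore demonstrate that the pipeline recovers a planted
structure–quality relationship under controlled conditions, not CASP-level
accuracy on real models.

The package's own validation scale is 20 targets × 10 models × 60 residues
(12 000 residues) for training and 4 unseen targets for held-out
evaluation; at that scale the end-to-end pipeline reaches held-out local
correlation ≈ 0.8 (asserted > 0.5).

## Evaluation statistics

Pooled, per-target and per-model Pearson correlations (constant vectors are
excluded from grouped means and counted); Fisher r-to-z two-sided tests
with variance 1/(n−3); GDT1 (sum of first-ranked models' GDT_TS) and
per-target selection Z-scores ((selected − mean)/sd, reported as 0 with a
warning for zero-variance targets); ROC/AUC for correct (<3 Å) vs incorrect
(>5 Å) residues with the 3–5 Å band excluded; top-fraction mean-deviation
curves; bootstrap support (1 000 target resamples with replacement by
default, ties counted 0.5, seeded).

## Numerical choices and degenerate inputs

* Exposure bins are closed on the right; a value exactly at a bin edge goes
  to the lower bin.  The buried/exposed classification for agreement
  features is strict: buried iff relative area < 25 %.
* Empty contact windows yield all-zero histogram blocks.
* Kabsch requires ≥ 3 non-collinear pairs; collinear sets raise.
* Consensus of a single-model ensemble raises; identical ensembles score
  exactly 1.
* All randomness flows through explicitly passed seeds; training is
  bit-reproducible given the seed.

## Known limitations

GDT_TS and the optimal-S superposition are heuristic searches; they give a
lower bound on the true optimum (dominance over the plain least-squares fit
is asserted, exhaustiveness is not claimed).  The dihedral secondary-
structure assigner ignores hydrogen bonding and will disagree with
STRIDE/DSSP on irregular elements.  The regressor is linear by design;
feature interactions are only captured through the engineered blocks.
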