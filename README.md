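# proqa

Single-model protein **model quality assessment**: predict, for every residue
of a protein structure model, how far it sits from the (unknown) native
structure — without ever seeing the native.

## The problem

Structure prediction pipelines produce many alternative models per target.
A quality assessment program ranks them and, more importantly, estimates
*absolute* local correctness: is this loop trustworthy, is that domain
misplaced?  Consensus scorers answer by comparing models to each other and
fail exactly where it matters (no consensus, or all models alike).  A
*single-model* method scores one model from its own coordinates and
sequence-derived features only, so it can also drive refinement.

## The method

The per-residue correctness measure is the S-score under the optimal
superposition between model and native,

    S_i = 1 / (1 + (d_i / d0)^2),        d0 = 3 Å,

where `d_i` is the Cα deviation of residue *i* and the superposition is the
one maximizing Σ S_i (found MaxSub-style by seed-and-extend).  S_i is 1 for
a perfect residue and 0.5 at exactly 3 Å.

A linear support-vector regressor predicts S_i from a fixed-length feature
vector describing the residue's environment in a 21-residue sliding window:

* atom–atom contact histogram over 13 atom classes (4 Å cutoff),
* residue–residue contact histogram over 6 residue groups (6 Å cutoff,
  >5 residues apart in sequence), **profile-weighted** by the per-position
  amino-acid frequencies of a sequence profile,
* side-chain exposure histogram (6 groups × 4 burial bins, profile-weighted),
* agreement between the model's secondary structure / burial and the ones
  predicted from sequence (windows of 21, 13, 5, 3 positions),
* two whole-model averages of those agreements — global context for a
  local prediction.

The global model quality is `Σ_i S_i / target_length`, a number in [0, 1].
A consensus score (mean pairwise S-score similarity within a model
ensemble) can be mixed in as `(1−k)·S_single + k·S_consensus` with k = 0.8.

Everything is testable offline: `proqa.fixtures` generates ideal-geometry
natives, perturbed model ensembles with known true quality, and matching
PSSM / secondary-structure / burial prediction files.

## Worked example

```bash
python examples/true_local_quality.py
```

```
residue   d (A)    S
      1    2.68  0.555
     11    5.98  0.201
     21    3.61  0.408
     31    2.20  0.651
     40    3.09  0.485

global S (sum S / target length): 0.518
GDT_TS:                           53.8
```

A 40-residue native was perturbed with a 2 Å smoothed displacement field;
residue 11 drifted ~6 Å from the native (S ≈ 0.2, unreliable), residue 31
stayed within 2.2 Å (S ≈ 0.65).  The global score 0.52 summarizes the whole
model; GDT_TS 53.8 is the CASP-standard global measure of the same model.

Other examples: `examples/train_and_score.py` (train the regressor on a
synthetic benchmark and score a held-out model), `examples/consensus_ranking.py`
(ensemble consensus plus the k = 0.8 combination),
`examples/benchmark_metrics.py` (correlations, Fisher z tests, ROC,
top-fraction curves, bootstrap support).

## Command line

```bash
proqa fixtures --out bench/ --targets 3            # synthetic benchmark dir
proqa features --pdb m.pdb --pssm t.pssm --ss2 t.ss2 --acc t.acc --out f.tsv
proqa train --out model.json                       # train on synthetic data
proqa score --model model.json --pdb m.pdb --pssm t.pssm --ss2 t.ss2 --acc t.acc
proqa consensus --models bench/models/
proqa eval --predictions pred.tsv --truth bench/truth.tsv
```

`score` prints the global score followed by per-residue predicted distances
(the S-to-distance view `d = d0·sqrt(1/S − 1)`), CASP QA style.

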