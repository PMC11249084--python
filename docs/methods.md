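# Methods

## Model

The encoder is a continuous-filter 3D message-passing network operating on
all-atom point clouds. A molecule enters as atomic numbers Z_i and Cartesian
coordinates R_i (Å); explicit hydrogens are added before force-field
embedding and kept, so the encoder always sees the all-atom geometry.
Chemical bonds are not used: neighborhoods are geometric, all ordered pairs
with 0 < d_ij ≤ cutoff. Distances are the only geometric input, which makes
the graph embedding exactly invariant under rigid motions and atom
permutation (asserted to 1e-5 relative tolerance in tests, and exact in
floating point for permutations).

Per interaction block, an atom-wise linear map precedes the continuous-filter
convolution, the filter is generated from Gaussian-RBF distance features by a
two-layer network, and the aggregated message passes through a two-layer
update network before the residual add; shifted softplus ln(0.5eˣ + 0.5) is
the nonlinearity throughout the encoder. The readout is an atom-wise
two-layer network summed over atoms. This is the reference regime of the
SchNet family; a loop-based dense re-implementation of the same equations
serves as the correctness oracle on small inputs (1e-6).

Parameter budget in closed form, with H = hidden width, K = RBF count,
L = blocks, E = embedding size, A = element-table rows:

    A·H + L·(4H² + K·H + 5H) + H·(H/2) + H/2 + (H/2)·E + E.

Defaults H=128, L=4, K=50, E=128, A=100 give 319,680 encoder parameters and
344,448 including the projection head, inside the ~0.5 M small-model regime
the method targets. The exact per-layer widths of the original experiments
are not printed anywhere authoritative; these defaults were chosen once to
land near that budget and are fully configurable.

## Conformer pools

Per molecule: oversample 30 distance-geometry embeddings (ETKDGv3, seeded),
minimize each with MMFF94, sort by energy, keep the 5 lowest. Key choices:

* **Rigid molecules.** A molecule with zero rotatable bonds has a single
  conformation up to minimization, so it gets a pool of one (both pairing
  strategies then return that conformer twice). Ring-flip conformers of
  rotor-free rings are ignored by this rule — a deliberate simplification.
* **No geometric deduplication by default.** MMFF94 minimization funnels
  many candidates into the same basin: butane's 30 candidates collapse onto
  the anti (−5.08 kcal/mol) and gauche (−4.29 kcal/mol) minima, and the five
  lowest-energy candidates of a flexible alkane are often all copies of the
  global minimum. Deduplicating at any RMSD threshold would therefore shrink
  pools of small molecules far below five, changing the sampling semantics of
  the method (the pool is defined by energy rank, not by geometric
  distinctness). An optional symmetric heavy-atom RMSD dedup
  (`dedup_rmsd`, greedy from lowest energy) is provided for users who want
  distinct basins.
* **Pair sampling.** conformer-R draws two distinct indices uniformly
  without replacement; the most stable conformer (index 0) is excluded from
  the eligible set whenever the pool has ≥3 members (configurable), which
  sharpens the contrast with conformer-S. Pools are built once and cached to
  SDF; pairs are re-drawn every epoch to maximize the geometric diversity
  each molecule exposes during pretraining.

## Contrastive objective

The projection head is a two-layer MLP with ReLU (output width = half the
embedding size); its output is not normalized — cosine similarity inside the
loss handles scale. The loss is the symmetric NT-Xent: all 2N views act as
anchors, the positive is the paired view, the denominator runs over the
other 2N−1 views, and the batch loss is the mean over anchors. Temperature
defaults to 0.1. Two analytic anchors pin the implementation: the loss of a
single pair is exactly 0, and a fully collapsed batch sits at ln(2N−1).
Baseline pairings (atom drop, attribute mask, position noise) perturb the
most stable conformer twice, independently, since those baselines do not use
the pool.

Training uses Adam at lr 10⁻³ with exponential per-epoch decay 0.95 (0.99
also supported), 300 epochs and batch 400 at full scale. One global seed
fans out to embedding, pairing, initialization and shuffling through named
SHA-256 substreams, so runs are bit-reproducible.

## Fine-tuning & evaluation

A linear head on h_G is trained end to end with the encoder (never frozen),
batch 32, 200 epochs, same optimizer schedule. Regression targets are
standardized with train-split statistics and predictions un-standardized
before metrics, so RMSE/MAE are in original units; classification trains
with binary cross-entropy on logits and reports ROC-AUC on the positive
score. Masked target entries never enter loss or metrics; multi-task scores
are the arithmetic mean of per-task metrics over tasks with usable entries
(a split whose task has a single class yields NaN for that task's AUC and is
skipped; if validation is never scoreable the final-epoch model is used).
Model selection is by best validation metric — epoch counts are fixed, so
some selection rule is needed and this is the conventional one.

The scaffold splitter groups molecules by canonical Bemis–Murcko scaffold
(chirality-aware by default), orders groups by size descending with
lexicographic tie-break, and greedily fills train, then validation, then
test capacities (0.8/0.1/0.1 of n) without splitting a group; a group larger
than every capacity falls back to train with a warning. Leakage (a scaffold
in two splits) is asserted in tests for every split the suite produces.

## Synthetic fixtures

The fixture generator emulates a small-molecule benchmark at desk scale:
random flexible chains (4-9 heavy atoms; C/N/O; optional methyl branch;
always ≥1 rotatable bond so conformer pools are non-trivial) mixed 70/30
with ring-bearing templates whose scaffolds repeat across molecules (so
scaffold groups have realistic size structure). A unique-scaffold mode draws
from 145 ring/linker templates with pairwise-distinct scaffolds, used to
test exact split fractions. Every generated molecule parses, embeds and
minimizes under MMFF94 by construction.

Regression targets are a fixed linear map of (all-atom count,
rotatable-bond count, heteroatom count) plus N(0, 0.5²) noise; multi-task
variants cycle fixed weight triples. Classification thresholds the
noise-free score at the median and flips 5% of labels. These targets are
learnable from 3D structure, so representation quality measurably moves
downstream error — which is what the pretraining-benefit experiments need.
What the fixtures do *not* emulate: real measurement noise structure,
activity cliffs, charged/aromatic chemistry beyond simple rings, tautomers,
and dataset-scale class imbalance. Passing the fixture experiments shows
the machinery behaves as designed, not that the method's benchmark numbers
transfer to any particular real dataset.

## Scaled-down experiment sizes

The pretraining-benefit experiment in the acceptance suite uses 200 fixture
molecules (pools from 10 candidates), an encoder at hidden 64 / 2 blocks /
25 RBFs / 5 Å cutoff, 15 pretraining epochs at batch 50, and fine-tuning for
60 epochs on 50 labeled molecules drawn from the train split of a scaffold
split of the same 200 molecules (validation and test splits of 20 each),
3 seeds. Pretraining on the full set while labeling a subset mirrors the
full-scale protocol, where the pretraining corpus is the downstream corpus.
These sizes are this package's desk-scale study conditions; the full-scale
defaults remain those stated above.

## Numerical notes

* The autodiff core is float64 throughout; scatter-adds use a sort +
  `reduceat` path; interior gradients are freed during the backward sweep
  and each batch's graph is dropped before the next is built, keeping peak
  memory a few hundred MB at the scaled-down sizes.
* The RBF grid spans [0, cutoff] with γ = 10 Å⁻²; a distance at a center
  gives feature value exactly 1, and empty neighborhoods contribute the zero
  vector, so an atom beyond the cutoff from everything behaves exactly like
  an isolated atom.
* NT-Xent exponentials are shifted by the row-wise off-diagonal maximum
  (a constant; gradient-exact) for stability at low temperature. Zero-norm
  projections raise rather than silently normalize.
* Affected-atom counts for drop/mask use round-half-to-even of
  ratio × n_atoms; dropping always retains at least one atom.
* Checkpoints pair an `.npz` weight container with a JSON sidecar holding
  the architecture config and a SHA-256 of the weights; loading verifies
  both.

## Known limitations

* No angular or torsional features, and no chirality awareness in the
  encoder: enantiomers and torsion-only differences beyond their distance
  signatures are invisible.
* MMFF94 coverage limits the chemistry (no parameters → molecule dropped
  with a warning).
* The rigid-molecule rule ignores ring-flip conformers.
* CPU-only NumPy training: practical for the small-model regime this method
  targets, not for large benchmarks at full batch sizes.
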