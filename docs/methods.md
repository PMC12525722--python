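# Methods

## Model

`ddilink` treats DDI prediction as binary link prediction on an
undirected drug network, with each drug additionally described by its
molecular graph. Two encoders produce commensurate `d`-dimensional
embeddings (both default to `d = 300`):

**Molecular (inter-view) encoder.** Atoms carry two categorical codes —
atomic-number index (vocabulary 119 plus one reserved mask token) and
chirality tag (4) — and bonds carry bond type (4) and bond direction
(3). Each GCN layer computes `S·X·W_l + B_l`, where
`S = D̂^{-1/2}(A+I)D̂^{-1/2}` is the symmetric degree-normalized bond
adjacency with self-loops and `B_l` aggregates learned bond-type and
bond-direction embeddings into each endpoint with the same edge
normalization. Every layer ends with a per-node layer normalization
(learned gain and bias); ReLU follows all but the last layer. Node
states are mean-pooled into the molecule vector. Default depth is 5
layers. The layer normalization is load-bearing: without it,
self-supervised pretraining inflates node-state magnitudes by an order
of magnitude, and the unnormalized K=5 moment-matching term (whose
gradients scale like the fourth power of the embedding scale) then
swamps the supervised loss during fine-tuning and training collapses.
It is deterministic, mode-free (no batch statistics) and permutation
invariant, so none of the encoder's contract properties change.

**Network (intra-view) encoder.** The embedding matrix `H` is propagated
over the DDI adjacency restricted to *training-split positive links*
(never validation or test links), using the same normalization:
`D = ReLU(Ŝ·ReLU(Ŝ·H·W0)·W1)`. Depth is configurable; the default is
the two-layer form written above. Drugs in held-out splits are isolated
nodes in this adjacency, so their rows reduce to a per-drug transform of
their own molecular embedding — exactly the inductive regime a new drug
would face.

**Predictor heads.** The pair embedding is the element-wise product,
which makes both heads symmetric under swapping the pair, as an
undirected relation requires. The main head is a two-layer MLP on
`d_i ⊙ d_j` with two output logits normalized by softmax; the auxiliary
head is a single linear layer on `h_i ⊙ h_j`. Reading the output
nonlinearity as a two-logit softmax (rather than per-logit sigmoid) is
the only interpretation under which the two-class cross-entropy and the
KL term between `p` and `q` are well-defined distributions; the product
fusion for the auxiliary head mirrors the main head's.

## Objective

`L = Ls + α·Lom + γ·Lfm` with defaults `α = 1`, `γ = 2`.

* `Ls` sums, over all labeled pairs in the batch (positives and sampled
  negatives — cross-entropy against `y` is only meaningful with negative
  labels), the cross-entropies of both heads. Natural logs; probabilities
  are clamped at `1e-12` before any log.
* `Lom` sums `KL(p ‖ q)` per pair, in that argument order (direction is
  configurable in the kernel). It distills the topology-aware main
  predictor's outputs into the molecular-only auxiliary path.
* `Lfm` is the central moment discrepancy between the rows of `D` and
  `H` for all drugs touched by the batch: the L2 gap of the means plus
  the L2 gaps of the component-wise central moments of orders 2..K,
  `K = 5`. The unnormalized form is used (no bounded-interval rescaling).
  The L2 norms have exact forward values; the gradient at an exactly
  zero norm is taken as zero.

Training uses Adam (learning rate 0.001) over mini-batches of labeled
pairs; both encoders run on the full drug set each step (n is small at
desk scale). Model selection keeps the weights with the best validation
AUROC, with early stopping (patience 10) — except that epochs before
`selection_start` (default 10) are warm-up and never eligible for
selection. This guard exists because an untrained model occasionally
flukes a high validation AUROC at the first epoch, which would freeze
training through the entire patience window and return effectively
random weights; the failure mode was observed as near-perfectly
*inverted* test rankings on single-scaffold test splits.

## Data handling

SMILES are parsed with RDKit; records that fail to parse are dropped and
reported. Scaffold splitting groups drugs by canonical Bemis–Murcko
scaffold SMILES (acyclic molecules form the single empty-scaffold
group), shuffles the groups with the split seed, and fills train until
it holds ≥ 80% of drugs, then valid until ≥ 10%, remainder to test —
whole groups are never divided, so split sizes deviate from 8:1:1 by at
most the largest group. Links inherit the most-held-out endpoint
(test > valid > train).

Negative sampling draws, per split, `round(ratio × positives)` uniform
non-adjacent unordered pairs (default ratio 1:1) *from the pairs
eligible for that split under the endpoint rule*. Because the
eligibility classes are disjoint (train: both endpoints train; valid:
≥ 1 valid and no test endpoint; test: ≥ 1 test endpoint), each split's
negatives are a deterministic function of that split's own drugs and
links — deleting the test links from the input leaves the training
trajectory bit-identical, which the test suite asserts.

Metrics: AUROC (rank probability, ties ½), AUPRC (step-wise
average-precision estimator), F1 and accuracy at a fixed 0.5 threshold
(the classification threshold is not part of the method; 0.5 is the
package's convention). Computed via scikit-learn and cross-checked
against exhaustive enumeration oracles in the tests.

## Self-supervised pretraining

All three strategies share the molecular encoder and Adam (defaults:
100 epochs, learning rate 0.001, batch size 256, 5 layers):

* **Masked-atom recovery** — `round(0.15·n_atoms)` atoms (minimum 1) per
  molecule are replaced by the mask token; a linear head on final node
  states predicts the original atomic-number index (cross-entropy over
  masked positions).
* **Edge prediction** — 15% of bonds (minimum 1) are hidden from message
  passing; scores of endpoint-state pairs must separate hidden bonds
  from an equal number of sampled non-bonded pairs (binary
  cross-entropy). Complete graphs contribute positives only.
* **Context prediction** — for a center atom, the main encoder embeds the
  substructure within `r1 = 4` hops and an auxiliary encoder embeds the
  context (atoms at hop distance in `(r1, r2 = 7]` together with the
  anchor atoms at exactly `r1` that border it); the center's state must
  score its own context (mean of anchor states) above contexts of other
  molecules in the batch (1 negative per positive, drawn in-batch).
  Molecules too small to have a non-empty context are skipped. Center
  atoms are drawn per (seed, molecule) — fixed across epochs — and
  samples are ordered by a stable per-molecule key, so the epoch loss is
  a smooth optimization curve rather than re-randomized each epoch.

Both discriminative objectives score a pair of state vectors by their
dot product scaled by `1/sqrt(d)` (the usual attention-style
temperature): unscaled dots grow with embedding width and can start
training tens of units deep in sigmoid saturation, where the first
epochs are spent escaping a few extreme pairs. The binary cross-entropy
is computed in its softplus form, `softplus(-s_pos) + softplus(s_neg)`,
whose gradient survives saturated scores (a clamped `log(sigmoid(s))`
silently zeroes the gradient exactly where learning is most needed).

Only the main encoder's weights are retained; by default they are
fine-tuned (not frozen) during DDI training, with a freeze flag.

## Synthetic benchmark

The generator emulates the three inputs a real study needs — a drug
table, a DDI edge list, an unlabeled corpus — with a *planted* signal:
every drug belongs to one of three structural families, and an unordered
pair is linked independently with probability 0.95 within a family and
0.02 across families. The families (N-heteroaromatics, carbocyclic
aromatics, saturated aliphatics; 8–11 distinct ring-system cores each,
selected round-robin, plus class-neutral decorations) are deliberately
recognizable from atom and bond statistics rather than from any single
scaffold, so scaffold splitting can hold out every test scaffold while
leaving the family — and hence the interaction signal — recoverable from
structure. This is precisely the inductive claim the model makes, which
is what makes end-to-end recovery a fair benchmark.

The 0.95/0.02 contrast was fixed analytically before any training: a
classifier reading the true class labels scores two-level probabilities,
and with three balanced classes its AUROC ceiling is ≈ 0.97 at
0.95/0.02 but only ≈ 0.85 at a milder 0.8/0.1 — too low to separate "the
model works" from "the benchmark is unlearnable". The benchmark is
dense (mean degree ≈ 65 at 200 drugs) and makes no attempt to match the
degree distributions of real DDI networks; conclusions from it concern
signal recovery, not real-data topology.

What passing the planted benchmark does **not** show: robustness to the
sparse, heavy-tailed connectivity of real DDI networks, to label noise,
to chemistry outside the fragment families, or to the weak and
entangled structure–interaction relationships of real pharmacology.

## Desk-scale problem sizes

Library defaults follow the full-scale configuration (300-dimensional,
5-layer encoders, 100-epoch pretraining). The bundled benchmark and the
acceptance script run everything at desk scale as the package's standard
verification setting: 32-dimensional embeddings (64 for the pretraining
sanity runs), 200 drugs, a 200-molecule corpus, 15-epoch pretraining,
and DDI training for up to 80 epochs with patience 15. Five-seed
repetition and both ablations (no feature/output matching; random
initialization instead of pretrained weights) are retained in full.

## Numerical choices

* Reverse-mode autodiff over float64 NumPy arrays; gradients of every
  primitive are verified against central finite differences.
* Glorot-uniform weight initialization; embedding tables N(0, 0.1).
* Adam with β = (0.9, 0.999), ε = 1e-8.
* All randomness flows from explicit seed sequences
  (`np.random.default_rng([seed, tag, ...])`); identical seeds give
  bit-identical results. Per-split and per-epoch streams are
  independent, so deleting one split's data cannot shift another's
  draws.
* Degenerate inputs: empty molecular graphs are rejected (nothing to
  pool); single-class label vectors raise in AUROC; zero-positive
  vectors raise in AUPRC; F1 uses the 0/0 := 0 convention; negative
  sampling reports a shortfall when non-edges run out.

## Known limitations

* The intra-view encoder defaults to the two-layer closed form; a
  three-layer variant is available via `intra_layers=3`.
* Pooling reads the final layer only (no cross-layer concatenation).
* CPU-only; complexity is quadratic in drugs for negative-sampling
  enumeration and dense adjacencies, fine for thousands of drugs but not
  beyond.
* Binary interaction existence only — no interaction typing, no 3D
  geometry, no salt/standardization pipeline, and stereochemistry enters
  only through the chirality tag.
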