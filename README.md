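# ddilink

Multi-view graph representation learning for drug–drug interaction (DDI)
link prediction, with self-supervised molecular pretraining and
scaffold-based evaluation.

## The problem

Co-administered drugs can change each other's pharmacological effect.
Predicting which drug pairs interact is a link-prediction problem on a
network whose nodes are drugs — but labeled interaction data is scarce,
and newly developed drugs often have chemical scaffolds never seen in
the training data. `ddilink` is for computational chemists and method
developers who want a complete, dependency-light implementation of a
two-view GCN approach to this problem, evaluated honestly under
out-of-distribution (scaffold) splits.

## The model

Two coupled graph views:

* **Inter-view (molecular)** — each drug's molecular graph (atoms as
  nodes, bonds as edges) is encoded by a multi-layer GCN with mean-pool
  readout into a vector `h_i`; stacked over n drugs this gives
  `H ∈ R^{n×d}`. The propagation rule per layer is
  `X ← act(D̂^{-1/2}(A+I)D̂^{-1/2} · X · W)` with bond-type/direction
  embeddings added into the aggregated messages. The encoder can be
  **pretrained self-supervised** on an unlabeled SMILES corpus by one of
  three objectives: context prediction, edge prediction, or masked-atom
  recovery.
* **Intra-view (DDI network)** — a second GCN propagates `H` over the
  normalized adjacency of *training-split* interaction links, producing
  topology-aware drug embeddings `D ∈ R^{n×d}`.

A pair `(i, j)` is scored by the main head
`p_ij = softmax(W_k · ReLU(W_I · (d_i ⊙ d_j) + b_I) + b_k)` and by an
auxiliary linear head `q_ij` on `h_i ⊙ h_j`. Training minimizes

```
L = Ls + α·Lom + γ·Lfm          (defaults α = 1, γ = 2)

Ls  = Σ_links CE(p, y) + CE(q, y)            supervised
Lom = Σ_links KL(p ‖ q)                      output-space matching
Lfm = ‖E(D)−E(H)‖₂ + Σ_{k=2}^{5} ‖C_k(D)−C_k(H)‖₂   feature-space matching (CMD)
```

where `C_k` is the component-wise k-th central moment. Evaluation uses
Bemis–Murcko scaffold splitting (8:1:1): no scaffold appears in more
than one split, and every test link involves a drug from an unseen
scaffold. The repetition protocol re-splits, re-samples negatives and
re-trains over five seeds, reporting mean ± std AUROC / AUPRC / F1 /
accuracy.

All tensor arithmetic (GCN layers, losses, Adam) runs on a small
reverse-mode autodiff engine over NumPy (`ddilink.autodiff`), verified
against finite differences in the test suite.

## Worked example

`examples/04_train_ddi_model.py` builds a 100-drug synthetic benchmark in
which drugs from the same structural family (N-heteroaromatic,
carboaromatic, or saturated aliphatic) interact with high probability and
cross-family pairs rarely do, pretrains the molecular encoder by
masked-atom recovery, and fine-tunes the full model:

```
epochs run 30, selected epoch 19
total loss 15268 -> 2275  (Ls 2167, Lom 57.2, Lfm 25.59)
train: auroc=0.906  auprc=0.905  f1=0.851  accuracy=0.828
valid: auroc=0.785  auprc=0.753  f1=0.805  accuracy=0.761
 test: auroc=0.825  auprc=0.827  f1=0.810  accuracy=0.779
```

Test AUROC of 0.825 on scaffold-held-out drugs means the model inferred
each unseen drug's structural family from its molecular graph alone and
used it to predict interactions — the planted signal, recovered
out-of-distribution. The other examples cover data generation (01),
scaffold splitting (02), pretraining (03) and the loss components (05).

## Command line

```bash
ddilink simulate --n-drugs 200 --n-corpus 200 --seed 0 --out-dir data/
ddilink pretrain --corpus data/corpus.smi --strategy masking_node --out enc.npz
ddilink split    --drugs data/drugs.csv --edges data/edges.csv --out-dir splits/
ddilink evaluate --drugs data/drugs.csv --edges data/edges.csv \
                 --pretrained enc.npz --out-dir results/
ddilink sweep    --drugs data/drugs.csv --edges data/edges.csv \
                 --parameter gamma --out-dir results/
```

Ablation switches: `--ablation no_pretrain no_om no_fm` (random encoder
initialization, drop output-space matching, drop feature-space matching).
Input formats: drug tables `drug_id,smiles`; edge lists
`drug_id_1,drug_id_2[,label]`; corpora one SMILES per line.

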