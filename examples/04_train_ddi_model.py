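"""Train the full two-view DDI model on a planted-signal benchmark.

Pipeline: pretrain the molecular GCN on an unlabeled corpus, scaffold-split
the drugs, sample negative pairs, then fine-tune both views under the
composite objective  L = Ls + alpha*Lom + gamma*Lfm  (alpha=1, gamma=2).
Desk-scale sizes keep this to about a minute.
"""

from ddilink.chem_graph import parse_smiles
from ddilink.pretrain import PretrainConfig, pretrain
from ddilink.synthdata import SyntheticSpec, generate_ddi, generate_molecules, generate_pretrain_corpus
from ddilink.train_eval import ExperimentConfig, prepare_split_data, train

spec = SyntheticSpec(n_drugs=100, seed=0)
mols = generate_molecules(spec)
drugs = [(d, s) for d, s, _ in mols]
network = generate_ddi(mols, spec)

corpus = [parse_smiles(s) for s in generate_pretrain_corpus(120, seed=1)]
pretrained, _ = pretrain(
    corpus, PretrainConfig(strategy="masking_node", emb_dim=32, epochs=10, batch_size=64, seed=0)
)

config = ExperimentConfig(emb_dim=32, epochs=40, patience=10, seeds=(0,))
data = prepare_split_data(drugs, network, seed=0, neg_ratio=config.neg_ratio)
result = train(config, data, pretrained=pretrained, seed=0)

first, last = result.loss_log[0], result.loss_log[-1]
print(f"epochs run {len(result.loss_log)}, selected epoch {result.best_epoch}")
print(f"total loss {first['total']:.0f} -> {last['total']:.0f}  "
      f"(Ls {last['Ls']:.0f}, Lom {last['Lom']:.1f}, Lfm {last['Lfm']:.2f})")
for split, m in result.metrics.items():
    print(f"{split:>5}: " + "  ".join(f"{k}={v:.3f}" for k, v in m.items()))
print("test metrics are computed on drugs whose scaffolds were never trained on;")
print("AUROC well above 0.5 means the model recovered the planted structural signal")
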