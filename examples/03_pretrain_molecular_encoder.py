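"""Self-supervised pretraining of the molecular GCN (desk scale).

Masks 15% of atoms per molecule and trains the encoder plus a linear
head to recover the masked atomic numbers; the learned weights transfer
to DDI fine-tuning. Swap ``strategy`` for "edge_pred" or "context_pred"
to try the other objectives.
"""

from ddilink.chem_graph import parse_smiles
from ddilink.pretrain import PretrainConfig, pretrain
from ddilink.synthdata import generate_pretrain_corpus

corpus = [parse_smiles(s) for s in generate_pretrain_corpus(120, seed=0)]
config = PretrainConfig(
    strategy="masking_node",
    emb_dim=32,       # 300 at full scale
    epochs=10,
    batch_size=64,
    mask_rate=0.15,
    seed=0,
)
encoder, log = pretrain(corpus, config)

print(f"pretrained on {len(corpus)} molecules, strategy={config.strategy}")
for rec in log[::3]:
    print(f"  epoch {rec['epoch']:2d}  masked-atom cross-entropy {rec['loss']:.3f}")
print("a falling cross-entropy means the encoder is learning which atom types")
print("fit each chemical context; the final weights seed the DDI model")
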