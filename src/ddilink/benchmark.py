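"""Desk-scale benchmark runs shared by the test suite and the acceptance script.

Everything here runs on synthetic data at reduced model size (32-dim
embeddings instead of the 300-dim default) so a full multi-seed
repetition protocol, its ablations and the pretraining sanity checks
complete in minutes on one CPU. The synthetic study conditions
themselves (200 drugs / 200-molecule corpus, the planted interaction
matrix, 8:1:1 scaffold splits, five seeds) are fixed by
:class:`~ddilink.synthdata.SyntheticSpec` defaults and the repetition
protocol; only the model width is desk-scaled.
"""

from __future__ import annotations

import numpy as np

from .chem_graph import parse_smiles
from .pretrain import (
    MaskingNodeStrategy,
    PretrainConfig,
    majority_baseline_accuracy,
    masked_atom_accuracy,
    pretrain,
)
from .synthdata import SyntheticSpec, generate_ddi, generate_molecules, generate_pretrain_corpus
from .train_eval import ExperimentConfig, run_experiment

DESK_DIM = 32
DESK_PRETRAIN_EPOCHS = 15
DESK_DDI_EPOCHS = 80


def desk_experiment_config(seed: int = 0, **overrides) -> ExperimentConfig:
    base = dict(
        emb_dim=DESK_DIM,
        epochs=DESK_DDI_EPOCHS,
        patience=15,
        seeds=tuple(int(s) for s in np.random.default_rng([seed, 0xBE9]).integers(0, 2**31, 5)),
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def desk_pretrain_config(seed: int = 0, strategy: str = "masking_node", **overrides) -> PretrainConfig:
    base = dict(
        strategy=strategy,
        emb_dim=DESK_DIM,
        epochs=DESK_PRETRAIN_EPOCHS,
        batch_size=64,
        seed=seed,
    )
    base.update(overrides)
    return PretrainConfig(**base)


def pretraining_sanity(seed: int = 0, n_corpus: int = 200, epochs: int = 20, emb_dim: int = 64) -> dict:
    """Run all three strategies on a synthetic corpus; report loss trajectories.

    For masking-node, also score held-out masked-atom recovery against the
    majority-class baseline computed from corpus atom-type frequencies.
    """
    corpus_smiles = generate_pretrain_corpus(n_corpus, seed=seed)
    graphs = [parse_smiles(s) for s in corpus_smiles]
    held_out = graphs[: n_corpus // 5]
    train_graphs = graphs[n_corpus // 5:]
    out: dict = {}
    for strategy in ("masking_node", "edge_pred", "context_pred"):
        cfg = PretrainConfig(
            strategy=strategy, emb_dim=emb_dim, epochs=epochs, batch_size=64, seed=seed
        )
        encoder, log = pretrain(train_graphs, cfg)
        out[strategy] = {
            "first_loss": log[0]["loss"],
            "final_loss": log[-1]["loss"],
            "log": log,
        }
        if strategy == "masking_node":
            encoder2, head2 = _pretrain_masking_with_head(train_graphs, cfg)
            out[strategy]["heldout_accuracy"] = masked_atom_accuracy(
                encoder2, head2, held_out, cfg, seed=seed + 1
            )
            out[strategy]["majority_baseline"] = majority_baseline_accuracy(graphs)
    return out


def _pretrain_masking_with_head(graphs, config: PretrainConfig):
    """Masking-node pretraining that also returns the trained linear head."""
    from .autodiff import Adam
    from .encoders import MolecularEncoder

    encoder = MolecularEncoder(
        hidden_dim=config.emb_dim, num_layers=config.num_layers, seed=config.seed
    )
    strategy = MaskingNodeStrategy(encoder, config)
    opt = Adam(strategy.parameters(), lr=config.learning_rate)
    for epoch in range(config.epochs):
        order = np.random.default_rng([config.seed, 0xB45, epoch]).permutation(len(graphs))
        for bi, start in enumerate(range(0, len(graphs), config.batch_size)):
            batch = [graphs[k] for k in order[start:start + config.batch_size]]
            rng = np.random.default_rng([config.seed, epoch, bi])
            loss = strategy.loss(batch, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return encoder, strategy.extra["head"]


def planted_signal_benchmark(
    seed: int = 0,
    variants: tuple = ("full", "no_fm_om", "no_pretrain"),
    n_drugs: int = 200,
) -> dict:
    """End-to-end recovery of the planted class-pair signal.

    Generates the synthetic drugs and DDI network, pretrains the molecular
    encoder once (masking-node, desk scale), then runs the five-seed
    protocol for the requested variants. Returns per-variant mean/std test
    metrics plus the mean test AUROC headline.
    """
    spec = SyntheticSpec(n_drugs=n_drugs, seed=seed)
    mols = generate_molecules(spec)
    drugs = [(d, s) for d, s, _ in mols]
    network = generate_ddi(mols, spec)
    corpus = [parse_smiles(s) for s in generate_pretrain_corpus(200, seed=seed + 1)]
    pretrained, _ = pretrain(corpus, desk_pretrain_config(seed=seed))
    out: dict = {}
    for variant in variants:
        if variant == "full":
            cfg = desk_experiment_config(seed)
        elif variant == "no_fm_om":
            cfg = desk_experiment_config(seed, ablation=("no_om", "no_fm"))
        elif variant == "no_pretrain":
            cfg = desk_experiment_config(seed, ablation=("no_pretrain",))
        else:
            raise ValueError(f"unknown variant {variant!r}")
        report, _results = run_experiment(cfg, drugs, network, pretrained=pretrained)
        out[variant] = {
            "report": report,
            "test_auroc_mean": report.mean("test", "auroc"),
            "test_auprc_mean": report.mean("test", "auprc"),
            "test_f1_mean": report.mean("test", "f1"),
            "test_accuracy_mean": report.mean("test", "accuracy"),
        }
    return out
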