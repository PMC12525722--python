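"""Self-supervised pretraining of the molecular encoder.

Three strategies, all trained with Adam on an unlabeled corpus:

* **ContextPred** — for a sampled center atom, the main encoder embeds
  the substructure within ``r1`` hops and the auxiliary encoder embeds
  the surrounding context (atoms at hop distance in ``(r1, r2]`` plus
  the anchor atoms at exactly ``r1`` that border it, whose states are
  averaged); a dot-product discriminator separates an atom's own context
  from contexts of other molecules in the batch.
* **EdgePred** — a seeded subset of bonds is hidden from message
  passing and a dot-product scorer must recover them against sampled
  non-bonded atom pairs.
* **MaskingNode** — a fraction of atoms is replaced by a reserved mask
  token and a linear head must recover the original atomic-number index
  from the final node states.

Only the main encoder's weights are kept as the pretrained molecular
representation; auxiliary encoders and heads are discarded.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .chem_graph import MolecularGraph, NUM_ATOM_TYPES
from .encoders import MolecularEncoder

logger = logging.getLogger(__name__)

STRATEGIES = ("context_pred", "edge_pred", "masking_node")


@dataclass
class PretrainConfig:
    strategy: str = "masking_node"
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 256
    num_layers: int = 5
    emb_dim: int = 300
    mask_rate: float = 0.15
    edge_hide_rate: float = 0.15
    r1: int = 4
    r2: int = 7
    neg_per_pos: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.mask_rate < 1:
            raise ValueError("mask_rate must lie in (0, 1)")
        if self.r1 >= self.r2:
            raise ValueError("require r1 < r2")
        if min(self.epochs, self.batch_size, self.num_layers, self.neg_per_pos) < 0:
            raise ValueError("config values must be positive")


@dataclass
class ContextExtraction:
    substructure_atoms: np.ndarray  # within r1 hops of center (incl. center)
    context_atoms: np.ndarray  # hop distance in (r1, r2]
    anchor_atoms: np.ndarray  # distance exactly r1, bordering the context
    center: int
    empty_context: bool


def _hop_distances(g: MolecularGraph, center: int) -> dict:
    G = nx.Graph()
    G.add_nodes_from(range(g.num_atoms))
    G.add_edges_from(map(tuple, g.edge_index))
    return nx.single_source_shortest_path_length(G, center)


def extract_context(g: MolecularGraph, center: int, r1: int, r2: int) -> ContextExtraction:
    """Substructure / context / anchor atom sets around one center atom."""
    if not 0 <= center < g.num_atoms:
        raise ValueError("center atom index out of range")
    if r1 >= r2:
        raise ValueError("require r1 < r2")
    dist = _hop_distances(g, center)
    sub = np.array(sorted(a for a, d in dist.items() if d <= r1), dtype=np.intp)
    ctx = np.array(sorted(a for a, d in dist.items() if r1 < d <= r2), dtype=np.intp)
    ctx_set = set(ctx.tolist())
    neighbors = {a: set() for a in dist}
    for i, j in g.edge_index:
        i, j = int(i), int(j)
        if i in neighbors and j in neighbors:
            neighbors[i].add(j)
            neighbors[j].add(i)
    anchors = np.array(
        sorted(
            a for a, d in dist.items()
            if d == r1 and neighbors[a] & ctx_set
        ),
        dtype=np.intp,
    )
    return ContextExtraction(
        substructure_atoms=sub,
        context_atoms=ctx,
        anchor_atoms=anchors,
        center=center,
        empty_context=len(ctx) == 0,
    )


def induced_subgraph(g: MolecularGraph, atoms: np.ndarray) -> tuple[MolecularGraph, dict]:
    """Induced subgraph on ``atoms``; returns (subgraph, old->new index map)."""
    atoms = np.asarray(atoms, dtype=np.intp)
    remap = {int(a): k for k, a in enumerate(atoms)}
    keep = [
        k for k, (i, j) in enumerate(g.edge_index)
        if int(i) in remap and int(j) in remap
    ]
    edges = np.array(
        [sorted((remap[int(i)], remap[int(j)])) for i, j in g.edge_index[keep]],
        dtype=np.int64,
    ).reshape(-1, 2)
    sub = MolecularGraph(
        node_features=g.node_features[atoms].copy(),
        edge_index=edges,
        edge_features=g.edge_features[keep].copy().reshape(-1, 2),
        source_smiles=g.source_smiles,
    )
    return sub, remap


def _flat_states(encoder: MolecularEncoder, batch: dict):
    """Node states reshaped to (B*A_max, d) for flat-index gathering."""
    X = encoder.node_states(batch)
    B, A = batch["atom_idx"].shape
    return ad.reshape(X, (B * A, encoder.hidden_dim)), A


def _bce_from_scores(pos, neg):
    """Mean binary cross-entropy: positives score high, negatives low.

    Written as softplus(-pos) + softplus(neg) — the stable form of
    -ln sigmoid(pos) - ln(1 - sigmoid(neg)) whose gradient survives
    saturated scores.
    """
    lp = ad.tsum(ad.softplus(ad.mul(pos, -1.0)))
    ln = ad.tsum(ad.softplus(neg))
    n = pos.data.size + neg.data.size
    return ad.mul(ad.add(lp, ln), 1.0 / n)


def _num_masked(mask_rate: float, num_atoms: int) -> int:
    return max(1, int(np.floor(mask_rate * num_atoms + 0.5)))


def masking_node_loss(
    encoder: MolecularEncoder,
    batch_graphs: list[MolecularGraph],
    config: PretrainConfig,
    head: Tensor | None = None,
    rng: np.random.Generator | None = None,
):
    """Cross-entropy of recovering masked atom types; mean over masked atoms."""
    rng = rng or np.random.default_rng(config.seed)
    if head is None:
        head = Tensor(np.zeros((encoder.hidden_dim, NUM_ATOM_TYPES)), True)
    consts, flat_pos, targets = [], [], []
    for b, g in enumerate(batch_graphs):
        k = _num_masked(config.mask_rate, g.num_atoms)
        masked = rng.choice(g.num_atoms, size=k, replace=False)
        consts.append(encoder.graph_constants(g, masked_atoms=masked))
        for a in masked:
            flat_pos.append((b, int(a)))
            targets.append(int(g.node_features[a, 0]))
    batch = encoder.batch_constants(consts)
    flat, A = _flat_states(encoder, batch)
    idx = np.array([b * A + a for b, a in flat_pos], dtype=np.intp)
    logits = ad.matmul(ad.take_rows(flat, idx), head)
    logp = ad.log_softmax(logits)
    onehot = np.zeros((len(targets), NUM_ATOM_TYPES))
    onehot[np.arange(len(targets)), targets] = 1.0
    ce = ad.mul(ad.tsum(ad.mul(logp, onehot)), -1.0 / len(targets))
    return ce


def edge_pred_loss(
    encoder: MolecularEncoder,
    batch_graphs: list[MolecularGraph],
    config: PretrainConfig,
    rng: np.random.Generator | None = None,
):
    """BCE of recovering hidden bonds against sampled non-bonded pairs."""
    rng = rng or np.random.default_rng(config.seed)
    consts, pos_pairs, neg_pairs = [], [], []
    graphs = [g for g in batch_graphs if g.num_edges >= 1]
    if not graphs:
        raise ValueError("edge prediction needs molecules with at least one bond")
    for b, g in enumerate(graphs):
        n_hide = max(1, int(np.floor(config.edge_hide_rate * g.num_edges + 0.5)))
        hidden = rng.choice(g.num_edges, size=n_hide, replace=False)
        consts.append(encoder.graph_constants(g, hidden_edges=hidden))
        bonded = {tuple(e) for e in g.edge_index.tolist()}
        non_bonded = [
            (u, v)
            for u in range(g.num_atoms)
            for v in range(u + 1, g.num_atoms)
            if (u, v) not in bonded
        ]
        for k in hidden:
            u, v = map(int, g.edge_index[k])
            pos_pairs.append((b, u, v))
        if non_bonded:
            picks = rng.choice(len(non_bonded), size=min(n_hide, len(non_bonded)), replace=False)
            for t in picks:
                u, v = non_bonded[t]
                neg_pairs.append((b, u, v))
        else:
            logger.info("molecule %d is complete; no negative pairs", b)
    batch = encoder.batch_constants(consts)
    flat, A = _flat_states(encoder, batch)

    def score(pairs):
        # temperature-scaled dot product: keeps scores O(1) regardless of
        # embedding width, so the BCE starts near ln 2 instead of saturated
        iu = np.array([b * A + u for b, u, _ in pairs], dtype=np.intp)
        iv = np.array([b * A + v for b, _, v in pairs], dtype=np.intp)
        dots = ad.tsum(ad.mul(ad.take_rows(flat, iu), ad.take_rows(flat, iv)), axis=1)
        return ad.mul(dots, 1.0 / np.sqrt(encoder.hidden_dim))

    pos = score(pos_pairs)
    if not neg_pairs:
        return ad.mul(ad.tsum(ad.softplus(ad.mul(pos, -1.0))), 1.0 / pos.data.size)
    return _bce_from_scores(pos, score(neg_pairs))


def context_pred_loss(
    main_encoder: MolecularEncoder,
    aux_encoder: MolecularEncoder,
    batch_graphs: list[MolecularGraph],
    config: PretrainConfig,
    rng: np.random.Generator | None = None,
):
    """BCE separating an atom's own context embedding from in-batch negatives."""
    rng = rng or np.random.default_rng(config.seed)
    # centers are drawn per (seed, molecule) — stable across epochs so the
    # epoch loss traces a smooth optimization curve; molecules are ordered
    # by the same stable key so in-batch negative pairing is reproducible
    def stable_key(g):
        return zlib.crc32(g.source_smiles.encode()) if g.source_smiles else g.num_atoms

    sub_consts, ctx_consts, center_pos, anchor_masks = [], [], [], []
    for g in sorted(batch_graphs, key=stable_key):
        center_rng = np.random.default_rng([config.seed, 0xCE7, stable_key(g)])
        center = int(center_rng.integers(g.num_atoms))
        ext = extract_context(g, center, config.r1, config.r2)
        if ext.empty_context or len(ext.anchor_atoms) == 0:
            continue
        sub_g, sub_map = induced_subgraph(g, ext.substructure_atoms)
        ctx_atoms = np.array(
            sorted(set(ext.context_atoms.tolist()) | set(ext.anchor_atoms.tolist())),
            dtype=np.intp,
        )
        ctx_g, ctx_map = induced_subgraph(g, ctx_atoms)
        sub_consts.append(main_encoder.graph_constants(sub_g))
        ctx_consts.append(aux_encoder.graph_constants(ctx_g))
        center_pos.append(sub_map[center])
        anchor_masks.append([ctx_map[int(a)] for a in ext.anchor_atoms])
    m = len(sub_consts)
    if m == 0:
        raise ValueError("no usable centers (all contexts empty) in this batch")
    sub_batch = main_encoder.batch_constants(sub_consts)
    ctx_batch = aux_encoder.batch_constants(ctx_consts)
    flat_sub, A_sub = _flat_states(main_encoder, sub_batch)
    flat_ctx, A_ctx = _flat_states(aux_encoder, ctx_batch)
    centers = ad.take_rows(
        flat_sub, np.array([b * A_sub + p for b, p in enumerate(center_pos)], dtype=np.intp)
    )
    # mean of anchor-node states per sample
    sel = np.zeros((m, ctx_batch["atom_idx"].shape[0] * A_ctx))
    for b, anchors in enumerate(anchor_masks):
        for p in anchors:
            sel[b, b * A_ctx + p] = 1.0 / len(anchors)
    contexts = ad.matmul(sel, flat_ctx)
    temp = 1.0 / np.sqrt(main_encoder.hidden_dim)  # keep scores O(1) in width
    pos = ad.mul(ad.tsum(ad.mul(centers, contexts), axis=1), temp)
    if m > 1:
        neg_scores = []
        for s in range(1, min(config.neg_per_pos, m - 1) + 1):
            perm = np.roll(np.arange(m), s)
            neg_scores.append(
                ad.mul(ad.tsum(ad.mul(centers, ad.take_rows(contexts, perm)), axis=1), temp)
            )
        neg = neg_scores[0]
        for extra in neg_scores[1:]:
            neg = ad.stack_rows([neg, extra])  # concatenated scores
        return _bce_from_scores(pos, neg)
    return ad.mul(ad.tsum(ad.softplus(ad.mul(pos, -1.0))), 1.0 / pos.data.size)


class _Strategy:
    def __init__(self, encoder: MolecularEncoder, config: PretrainConfig):
        self.encoder = encoder
        self.config = config
        self.extra: dict[str, Tensor] = {}

    def parameters(self):
        return self.encoder.tensors() + list(self.extra.values())

    def loss(self, graphs, rng):  # pragma: no cover - abstract
        raise NotImplementedError


class MaskingNodeStrategy(_Strategy):
    def __init__(self, encoder, config):
        super().__init__(encoder, config)
        rng = np.random.default_rng([config.seed, 0x3A5])
        self.extra["head"] = Tensor(
            rng.normal(0, 0.1, (encoder.hidden_dim, NUM_ATOM_TYPES)), True
        )

    def loss(self, graphs, rng):
        return masking_node_loss(self.encoder, graphs, self.config, self.extra["head"], rng)


class EdgePredStrategy(_Strategy):
    def loss(self, graphs, rng):
        return edge_pred_loss(self.encoder, graphs, self.config, rng)


class ContextPredStrategy(_Strategy):
    def __init__(self, encoder, config):
        super().__init__(encoder, config)
        self.aux = MolecularEncoder(
            hidden_dim=encoder.hidden_dim, num_layers=max(1, config.num_layers - 2),
            seed=config.seed + 1,
        )

    def parameters(self):
        return super().parameters() + self.aux.tensors()

    def loss(self, graphs, rng):
        return context_pred_loss(self.encoder, self.aux, graphs, self.config, rng)


_STRATEGY_CLS = {
    "masking_node": MaskingNodeStrategy,
    "edge_pred": EdgePredStrategy,
    "context_pred": ContextPredStrategy,
}


def pretrain(
    corpus: list[MolecularGraph],
    config: PretrainConfig,
) -> tuple[MolecularEncoder, list[dict]]:
    """Run the selected strategy on the corpus; returns (encoder, loss log).

    Fully seeded: the encoder init, batch order, and every masking/hiding/
    negative draw derive from ``config.seed``; ``epochs = 0`` returns the
    freshly initialized encoder untouched.
    """
    config.validate()
    if not corpus:
        raise ValueError("empty pretraining corpus")
    encoder = MolecularEncoder(
        hidden_dim=config.emb_dim, num_layers=config.num_layers, seed=config.seed
    )
    strategy = _STRATEGY_CLS[config.strategy](encoder, config)
    opt = Adam(strategy.parameters(), lr=config.learning_rate)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = np.random.default_rng([config.seed, 0xB45, epoch]).permutation(len(corpus))
        losses = []
        for bi, start in enumerate(range(0, len(corpus), config.batch_size)):
            graphs = [corpus[k] for k in order[start:start + config.batch_size]]
            rng = np.random.default_rng([config.seed, epoch, bi])
            try:
                loss = strategy.loss(graphs, rng)
            except ValueError:
                continue  # e.g. a batch without usable contexts
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        mean = float(np.mean(losses)) if losses else float("nan")
        log.append({"epoch": epoch, "loss": mean})
        logger.info("pretrain %s epoch %d loss %.4f", config.strategy, epoch, mean)
    return encoder, log


def masked_atom_accuracy(
    encoder: MolecularEncoder,
    head: Tensor,
    graphs: list[MolecularGraph],
    config: PretrainConfig,
    seed: int = 0,
) -> float:
    """Fraction of masked atoms whose type the head recovers (argmax)."""
    rng = np.random.default_rng([seed, 0xACC])
    consts, flat_pos, targets = [], [], []
    for b, g in enumerate(graphs):
        k = _num_masked(config.mask_rate, g.num_atoms)
        masked = rng.choice(g.num_atoms, size=k, replace=False)
        consts.append(encoder.graph_constants(g, masked_atoms=masked))
        for a in masked:
            flat_pos.append((b, int(a)))
            targets.append(int(g.node_features[a, 0]))
    batch = encoder.batch_constants(consts)
    flat, A = _flat_states(encoder, batch)
    idx = np.array([b * A + a for b, a in flat_pos], dtype=np.intp)
    logits = np.matmul(ad.take_rows(flat, idx).data, head.data)
    return float(np.mean(logits.argmax(axis=1) == np.array(targets)))


def majority_baseline_accuracy(graphs: list[MolecularGraph]) -> float:
    """Accuracy of always predicting the corpus's most common atom type."""
    counts = np.bincount(
        np.concatenate([g.node_features[:, 0] for g in graphs]), minlength=NUM_ATOM_TYPES
    )
    return float(counts.max() / counts.sum())
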