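"""Graph-convolution encoders for both views.

Two encoders share the same propagation rule ``act(S X W)`` with
``S = Deg^{-1/2} (A + I) Deg^{-1/2}``:

* the **molecular encoder** embeds per-atom categorical features, runs a
  stack of GCN layers over the bond adjacency (bond-type and
  bond-direction embeddings are added into the aggregated messages with
  the same degree normalization), and mean-pools atom states into one
  molecule-level vector per drug;
* the **network encoder** propagates the matrix of molecule-level
  vectors H over the DDI adjacency restricted to training links,
  yielding the topology-aware drug embeddings D.

Both operate on the autodiff ``Tensor`` type during training; all public
helpers also accept plain ndarrays and then return ndarrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem_graph import (
    DDINetwork,
    MASK_ATOM_INDEX,
    MolecularGraph,
    NUM_ATOM_TYPES,
    NUM_BOND_DIRS,
    NUM_BOND_TYPES,
    NUM_CHIRALITY_TAGS,
)

CHECKPOINT_VERSION = 1


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization ``Deg^{-1/2} (A + I) Deg^{-1/2}``.

    ``Deg`` is the diagonal row-sum of ``A + I``; rows of isolated nodes
    therefore reduce to identity rows.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    Ahat = A + np.eye(A.shape[0])
    dinv = 1.0 / np.sqrt(Ahat.sum(axis=1))
    return Ahat * dinv[:, None] * dinv[None, :]


def gcn_layer(S, X, W, activate: bool = True):
    """One propagation step ``act(S X W)``; ReLU when ``activate``."""
    out = ad.matmul(ad.matmul(S, X), W)
    return ad.relu(out) if activate else out


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class GCNEncoderParams:
    """Weight container for one encoder; values are autodiff Tensors."""

    params: dict = field(default_factory=dict)
    hidden_dim: int = 300
    num_layers: int = 5

    def tensors(self) -> list:
        return list(self.params.values())

    def copy_arrays(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: dict) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(arrays[k], dtype=np.float64).copy()


class MolecularEncoder(GCNEncoderParams):
    """Multi-layer GCN over atoms with mean-pool readout.

    Parameters: an atom-type embedding table (with one reserved row for
    the mask token), a chirality embedding table, and per layer a weight
    matrix plus bond-type/bond-direction message embeddings. Each layer
    is followed by a per-node layer normalization (learned gain/bias),
    which keeps node-state magnitudes stable through depth and through
    pretraining — without it, self-supervised pretraining inflates the
    embedding scale and the unnormalized K=5 moment-matching term then
    dominates downstream fine-tuning. ReLU after every layer except the
    last.
    """

    LN_EPS = 1e-5

    def __init__(self, hidden_dim: int = 300, num_layers: int = 5, seed: int = 0):
        super().__init__(hidden_dim=hidden_dim, num_layers=num_layers)
        rng = np.random.default_rng([seed, 0xE14C])
        d = hidden_dim
        p = {}
        p["atom_emb"] = Tensor(rng.normal(0, 0.1, (NUM_ATOM_TYPES + 1, d)), True)
        p["chir_emb"] = Tensor(rng.normal(0, 0.1, (NUM_CHIRALITY_TAGS, d)), True)
        for l in range(num_layers):
            p[f"W{l}"] = Tensor(_glorot(rng, (d, d)), True)
            p[f"bond_type{l}"] = Tensor(rng.normal(0, 0.1, (NUM_BOND_TYPES, d)), True)
            p[f"bond_dir{l}"] = Tensor(rng.normal(0, 0.1, (NUM_BOND_DIRS, d)), True)
            p[f"ln_gain{l}"] = Tensor(np.ones(d), True)
            p[f"ln_bias{l}"] = Tensor(np.zeros(d), True)
        self.params = p

    def _layer_norm(self, X, l: int):
        mu = ad.tmean(X, axis=-1, keepdims=True)
        centered = ad.sub(X, mu)
        var = ad.tmean(ad.power(centered, 2), axis=-1, keepdims=True)
        normed = ad.div(centered, ad.sqrt(ad.add(var, self.LN_EPS)))
        return ad.add(ad.mul(normed, self.params[f"ln_gain{l}"]), self.params[f"ln_bias{l}"])

    # -- graph constants ------------------------------------------------
    @staticmethod
    def graph_constants(
        g: MolecularGraph,
        hidden_edges=None,
        masked_atoms=None,
    ) -> dict:
        """Precompute the constant matrices one molecule contributes.

        ``hidden_edges`` (edge row indices) are removed from message
        passing; ``masked_atoms`` have their atom-type index replaced by
        the mask token. Returns S (normalized adjacency), per-node bond
        incidence matrices weighted by the same normalization, and the
        categorical index vectors.
        """
        n = g.num_atoms
        atom_idx = g.node_features[:, 0].copy()
        if masked_atoms is not None and len(masked_atoms):
            atom_idx[np.asarray(masked_atoms)] = MASK_ATOM_INDEX
        keep = np.ones(g.num_edges, dtype=bool)
        if hidden_edges is not None and len(hidden_edges):
            keep[np.asarray(hidden_edges)] = False
        A = np.zeros((n, n))
        for (i, j) in g.edge_index[keep]:
            A[i, j] = A[j, i] = 1.0
        S = normalize_adjacency(A)
        C_type = np.zeros((n, NUM_BOND_TYPES))
        C_dir = np.zeros((n, NUM_BOND_DIRS))
        for (i, j), (bt, bd) in zip(g.edge_index[keep], g.edge_features[keep]):
            C_type[i, bt] += S[i, j]
            C_type[j, bt] += S[j, i]
            C_dir[i, bd] += S[i, j]
            C_dir[j, bd] += S[j, i]
        return {
            "S": S,
            "C_type": C_type,
            "C_dir": C_dir,
            "atom_idx": atom_idx,
            "chir_idx": g.node_features[:, 1],
            "n": n,
        }

    @staticmethod
    def batch_constants(consts: list) -> dict:
        """Pad a list of per-molecule constants into batched arrays."""
        B = len(consts)
        A_max = max(c["n"] for c in consts)
        S = np.zeros((B, A_max, A_max))
        C_type = np.zeros((B, A_max, NUM_BOND_TYPES))
        C_dir = np.zeros((B, A_max, NUM_BOND_DIRS))
        atom_idx = np.zeros((B, A_max), dtype=np.intp)
        chir_idx = np.zeros((B, A_max), dtype=np.intp)
        mask = np.zeros((B, A_max))
        for b, c in enumerate(consts):
            n = c["n"]
            S[b, :n, :n] = c["S"]
            C_type[b, :n] = c["C_type"]
            C_dir[b, :n] = c["C_dir"]
            atom_idx[b, :n] = c["atom_idx"]
            chir_idx[b, :n] = c["chir_idx"]
            mask[b, :n] = 1.0
        return {
            "S": S,
            "C_type": C_type,
            "C_dir": C_dir,
            "atom_idx": atom_idx,
            "chir_idx": chir_idx,
            "mask": mask,
            "counts": mask.sum(axis=1),
        }

    # -- forward --------------------------------------------------------
    def node_states(self, batch: dict):
        """Final-layer per-atom states, shape (B, A_max, d).

        Padded rows receive arbitrary values; always apply ``batch['mask']``
        before reading them.
        """
        p = self.params
        X = ad.add(
            ad.take_rows(p["atom_emb"], batch["atom_idx"]),
            ad.take_rows(p["chir_emb"], batch["chir_idx"]),
        )
        for l in range(self.num_layers):
            msg = ad.matmul(ad.matmul(batch["S"], X), p[f"W{l}"])
            bond = ad.add(
                ad.matmul(batch["C_type"], p[f"bond_type{l}"]),
                ad.matmul(batch["C_dir"], p[f"bond_dir{l}"]),
            )
            X = self._layer_norm(ad.add(msg, bond), l)
            if l < self.num_layers - 1:
                X = ad.relu(X)
        return X

    def encode_batch(self, batch: dict):
        """Mean-pooled molecule-level embeddings, shape (B, d)."""
        X = self.node_states(batch)
        mask = batch["mask"][:, :, None]
        pooled = ad.tsum(ad.mul(X, mask), axis=1)
        return ad.mul(pooled, (1.0 / batch["counts"])[:, None])

    def encode_graphs(self, graphs: list):
        consts = [self.graph_constants(g) for g in graphs]
        return self.encode_batch(self.batch_constants(consts))


def encode_molecule(g: MolecularGraph, params: MolecularEncoder) -> np.ndarray:
    """Molecule-level embedding vector (length ``params.hidden_dim``)."""
    if g.num_atoms < 1:
        raise ValueError("cannot pool an empty graph")
    return params.encode_graphs([g]).data[0]


class NetworkEncoder(GCNEncoderParams):
    """Multi-layer GCN over the DDI network (default 2 layers).

    Propagates the molecule-level embedding matrix H through the
    normalized train-link adjacency: ``D = ReLU(S ReLU(S H W0) W1)``.
    """

    def __init__(self, hidden_dim: int = 300, num_layers: int = 2, seed: int = 0):
        super().__init__(hidden_dim=hidden_dim, num_layers=num_layers)
        rng = np.random.default_rng([seed, 0x0DD1])
        self.params = {
            f"W{l}": Tensor(_glorot(rng, (hidden_dim, hidden_dim)), True)
            for l in range(num_layers)
        }

    def forward(self, S: np.ndarray, H):
        X = H
        for l in range(self.num_layers):
            X = gcn_layer(S, X, self.params[f"W{l}"], activate=True)
        return X


def train_adjacency(network: DDINetwork, link_split: dict | None = None) -> np.ndarray:
    """DDI adjacency restricted to train-split positive links (no leakage)."""
    if link_split is None:
        return network.adjacency.astype(np.float64)
    A = np.zeros((network.n, network.n))
    for i, j, y in network.labeled_pairs:
        if y == 1 and link_split.get((i, j)) == "train":
            A[i, j] = A[j, i] = 1.0
    return A


def encode_network(
    H,
    network: DDINetwork,
    params: NetworkEncoder,
    link_split: dict | None = None,
):
    """Intra-view drug embeddings D (n x d) from H and the train links."""
    Hd = H.data if isinstance(H, Tensor) else np.asarray(H)
    if Hd.shape[0] != network.n:
        raise ValueError("H rows must align with network drugs")
    if Hd.shape[1] != params.hidden_dim:
        raise ValueError("H feature dimension mismatch with encoder")
    S = normalize_adjacency(train_adjacency(network, link_split))
    return params.forward(S, H)


# -- checkpoints --------------------------------------------------------


def save_checkpoint(path, encoder: GCNEncoderParams, extra_meta: dict | None = None):
    """Persist encoder weights + featurization vocabulary sizes (.npz)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": type(encoder).__name__,
        "hidden_dim": encoder.hidden_dim,
        "num_layers": encoder.num_layers,
        "vocab": {
            "atom_types": NUM_ATOM_TYPES,
            "chirality_tags": NUM_CHIRALITY_TAGS,
            "bond_types": NUM_BOND_TYPES,
            "bond_dirs": NUM_BOND_DIRS,
        },
    }
    if extra_meta:
        meta.update(extra_meta)
    arrays = {f"param/{k}": v.data for k, v in encoder.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[GCNEncoderParams, dict]:
    """Load a checkpoint; returns (encoder, meta)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        arrays = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cls = {"MolecularEncoder": MolecularEncoder, "NetworkEncoder": NetworkEncoder}[meta["kind"]]
    enc = cls(hidden_dim=meta["hidden_dim"], num_layers=meta["num_layers"])
    enc.load_arrays(arrays)
    return enc, meta
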