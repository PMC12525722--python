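"""Link predictor heads: fuse per-drug embeddings, output interaction probabilities.

For an unordered drug pair (i, j) the pair embedding is the element-wise
product of the two per-drug vectors, which makes both heads symmetric in
their arguments — as required for an undirected interaction relation.

* main head (intra-view): two-layer MLP on ``d_i * d_j``
  (ReLU hidden layer, 2 output logits);
* auxiliary head (inter-view): single linear layer on ``h_i * h_j``.

Both heads emit a 2-class probability pair via normalized exponentials
of the logits, so p and q live on the 2-simplex and can be compared with
cross-entropy and KL divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class LinkPredictorParams:
    """Weights of the main (2-layer) and auxiliary (linear) heads."""

    params: dict = field(default_factory=dict)
    dim: int = 300

    @classmethod
    def init(cls, dim: int = 300, hidden: int | None = None, seed: int = 0):
        rng = np.random.default_rng([seed, 0x11A7])
        h = hidden or dim

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        p = {
            "W_I": Tensor(glorot((dim, h)), True),
            "b_I": Tensor(np.zeros(h), True),
            "W_k": Tensor(glorot((h, 2)), True),
            "b_k": Tensor(np.zeros(2), True),
            "aux_W": Tensor(glorot((dim, 2)), True),
            "aux_b": Tensor(np.zeros(2), True),
        }
        return cls(params=p, dim=dim)

    def tensors(self):
        return list(self.params.values())

    def copy_arrays(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: dict) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(arrays[k], dtype=np.float64).copy()


def fuse(d_i, d_j):
    """Pair embedding: element-wise product (symmetric in its arguments)."""
    di = d_i.data if isinstance(d_i, Tensor) else np.asarray(d_i)
    dj = d_j.data if isinstance(d_j, Tensor) else np.asarray(d_j)
    if di.shape != dj.shape:
        raise ValueError("embedding length mismatch")
    return ad.mul(d_i, d_j)


def main_logp(I, params: LinkPredictorParams):
    """Log-probabilities of the main head for pair embeddings I (m x d)."""
    p = params.params
    hidden = ad.relu(ad.add(ad.matmul(I, p["W_I"]), p["b_I"]))
    logits = ad.add(ad.matmul(hidden, p["W_k"]), p["b_k"])
    return ad.log_softmax(logits)


def aux_logp(F, params: LinkPredictorParams):
    """Log-probabilities of the auxiliary head for fused pairs F (m x d)."""
    p = params.params
    logits = ad.add(ad.matmul(F, p["aux_W"]), p["aux_b"])
    return ad.log_softmax(logits)


def predict_main(I_ij, params: LinkPredictorParams) -> np.ndarray:
    """Interaction probability pair p for one pair embedding."""
    I_ij = np.asarray(I_ij, dtype=np.float64)
    if not np.all(np.isfinite(I_ij)):
        raise ValueError("non-finite pair embedding")
    return np.exp(main_logp(I_ij[None, :], params).data[0])


def predict_aux(h_i, h_j, params: LinkPredictorParams) -> np.ndarray:
    """Auxiliary probability pair q from the two molecular embeddings."""
    F = np.asarray(fuse(h_i, h_j), dtype=np.float64)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite fused embedding")
    return np.exp(aux_logp(F[None, :], params).data[0])
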