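"""Training objective: supervised loss, output-space and feature-space matching.

The composite objective is

    L = Ls + alpha * Lom + gamma * Lfm

with

* ``Ls``  — summed two-class cross-entropy of both predictors against the
  link labels: sum over links of CE(p, y) + CE(q, y);
* ``Lom`` — output-space matching: sum over links of KL(p || q), pulling
  the auxiliary (molecular-view) predictor toward the main
  (network-view) predictor's output distribution;
* ``Lfm`` — feature-space matching: the central moment discrepancy (CMD)
  between the two drug-embedding distributions D and H, i.e. the L2 gap
  of their means plus the L2 gaps of their component-wise central
  moments of orders 2..K (default K = 5, unnormalized form).

Defaults ``alpha = 1`` and ``gamma = 2``. All functions accept plain
ndarrays (returning floats) or autodiff Tensors (returning Tensors, for
training). Natural logarithms throughout; probabilities are clamped at
``EPS = 1e-12`` before any log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-12


@dataclass
class LossBreakdown:
    """The three loss components and their weighted sum for one batch."""

    Ls: float
    Lom: float
    Lfm: float
    total: float
    alpha: float = 1.0
    gamma: float = 2.0
    K: int = 5

    def as_dict(self) -> dict:
        return {
            "Ls": self.Ls,
            "Lom": self.Lom,
            "Lfm": self.Lfm,
            "total": self.total,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "K": self.K,
        }


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _log_clamped(x):
    return ad.log(ad.clamp_min(x, EPS))


def cross_entropy_matrix(P, y):
    """Sum over rows of ``-ln P[row, y_row]`` for probability rows P."""
    y = np.asarray(y, dtype=np.intp)
    onehot = np.zeros((len(y), 2))
    onehot[np.arange(len(y)), y] = 1.0
    ce = ad.mul(_log_clamped(P), onehot)
    return ad.mul(ad.tsum(ce), -1.0)


def supervised_loss(preds):
    """Eq.-style supervised term: sum over links of CE(p, y) + CE(q, y).

    ``preds`` is a list of ``(p, q, y)`` with p, q probability pairs and
    y in {0, 1}.
    """
    P = ad.stack_rows([p for p, _, _ in preds])
    Q = ad.stack_rows([q for _, q, _ in preds])
    y = [int(t[2]) for t in preds]
    return ad.add(cross_entropy_matrix(P, y), cross_entropy_matrix(Q, y))


def kl_matrix(P, Q):
    """Sum over rows of KL(p_row || q_row), natural log, 0*ln 0 := 0."""
    Pd = P.data if isinstance(P, Tensor) else np.asarray(P, dtype=np.float64)
    # 0 * ln 0 handled by the clamp: the p factor is exactly 0 there
    term = ad.mul(P, ad.sub(_log_clamped(P), _log_clamped(Q)))
    if not _is_t(P, Q):
        term = np.where(Pd > 0, term, 0.0)
    return ad.tsum(term)


def output_matching_loss(preds, direction: str = "pq"):
    """Output-space matching: sum over links of KL(p || q).

    ``direction='qp'`` reverses the arguments (KL(q || p)).
    """
    if direction not in ("pq", "qp"):
        raise ValueError("direction must be 'pq' or 'qp'")
    P = ad.stack_rows([p for p, _ in preds])
    Q = ad.stack_rows([q for _, q in preds])
    return kl_matrix(P, Q) if direction == "pq" else kl_matrix(Q, P)


def central_moments(X, k: int):
    """Component-wise k-th central moment over the rows of X (k >= 2)."""
    if int(k) < 2:
        raise ValueError("central moments defined here for k >= 2")
    Xd = X.data if isinstance(X, Tensor) else np.asarray(X, dtype=np.float64)
    if Xd.shape[0] < 1:
        raise ValueError("need at least one row")
    mean = ad.tmean(X, axis=0)
    dev = ad.sub(X, mean)
    return ad.tmean(ad.power(dev, int(k)), axis=0)


def cmd_loss(D, H, K: int = 5):
    """Central moment discrepancy between the row distributions of D and H.

    ``||E(D) - E(H)||_2 + sum_{k=2}^{K} ||C_k(D) - C_k(H)||_2`` with E and
    C_k component-wise over rows; unnormalized form.
    """
    Dd = D.data if isinstance(D, Tensor) else np.asarray(D, dtype=np.float64)
    Hd = H.data if isinstance(H, Tensor) else np.asarray(H, dtype=np.float64)
    if Dd.shape[1] != Hd.shape[1]:
        raise ValueError("D and H must have the same number of columns")
    out = ad.l2norm(ad.sub(ad.tmean(D, axis=0), ad.tmean(H, axis=0)))
    for k in range(2, int(K) + 1):
        out = ad.add(out, ad.l2norm(ad.sub(central_moments(D, k), central_moments(H, k))))
    return out


def total_loss(Ls, Lom, Lfm, alpha: float = 1.0, gamma: float = 2.0, K: int = 5):
    """Weighted sum L = Ls + alpha*Lom + gamma*Lfm.

    Returns a :class:`LossBreakdown` when inputs are floats; a Tensor
    (the differentiable total) when any input is a Tensor.
    """
    if alpha < 0 or gamma < 0:
        raise ValueError("alpha and gamma must be non-negative")
    total = ad.add(ad.add(Ls, ad.mul(float(alpha), Lom)), ad.mul(float(gamma), Lfm))
    if _is_t(Ls, Lom, Lfm):
        return total
    return LossBreakdown(
        Ls=float(Ls), Lom=float(Lom), Lfm=float(Lfm), total=float(total),
        alpha=float(alpha), gamma=float(gamma), K=int(K),
    )
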