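"""End-to-end DDI training, evaluation metrics and the repetition protocol.

One training repetition: scaffold-split the drugs 8:1:1, inherit link
splits from endpoints, sample negatives per split, then optimize the
composite objective with Adam. Each epoch encodes every drug's molecular
graph (fine-tuning the pretrained weights unless frozen), propagates the
resulting matrix H through the DDI-network encoder restricted to
train-split links, scores labeled train pairs with both predictor heads
and steps on ``Ls + alpha*Lom + gamma*Lfm``. Model selection keeps the
weights with the best validation AUROC (early stopping on patience).

``run_experiment`` repeats this over several seeds — each seed redraws
the scaffold shuffle, the negatives and the weight initialization — and
reports mean and standard deviation of AUROC/AUPRC/F1/accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import autodiff as ad
from .autodiff import Adam
from .chem_graph import (
    DDINetwork,
    SplitAssignment,
    parse_smiles,
    sample_negative_links,
    scaffold_split,
    split_links,
)
from .ddi_predictor import LinkPredictorParams, aux_logp, main_logp
from .encoders import MolecularEncoder, NetworkEncoder, encode_network
from .objectives import LossBreakdown, cmd_loss, cross_entropy_matrix, kl_matrix, total_loss

logger = logging.getLogger(__name__)

METRICS = ("auroc", "auprc", "f1", "accuracy")
ABLATIONS = ("no_pretrain", "no_om", "no_fm")


# -- metrics ------------------------------------------------------------


def auroc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under precision-recall via the step-wise average-precision estimator."""
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, scores))


def f1_accuracy(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """F1 (0/0 := 0) and accuracy after binarizing scores at ``threshold``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    acc = float(np.mean(pred == labels)) if len(labels) else 0.0
    return float(f1), acc


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict:
    f1, acc = f1_accuracy(scores, labels, threshold)
    return {
        "auroc": auroc(scores, labels),
        "auprc": auprc(scores, labels),
        "f1": f1,
        "accuracy": acc,
    }


# -- configuration / data -----------------------------------------------


@dataclass
class ExperimentConfig:
    learning_rate: float = 0.001
    epochs: int = 100
    patience: int = 10
    selection_start: int = 10  # first epoch eligible for model selection
    alpha: float = 1.0
    gamma: float = 2.0
    K: int = 5
    emb_dim: int = 300
    mol_layers: int = 5
    intra_layers: int = 2
    batch_size: int = 1024  # labeled pairs per step; encoders run on all drugs
    neg_ratio: float = 1.0
    threshold: float = 0.5
    freeze_pretrained: bool = False
    ablation: tuple = ()
    seeds: tuple = (0, 1, 2, 3, 4)

    def validate(self) -> None:
        if not self.seeds:
            raise ValueError("need at least one seed")
        if self.learning_rate <= 0 or self.neg_ratio <= 0:
            raise ValueError("rates must be positive")
        for a in self.ablation:
            if a not in ABLATIONS:
                raise ValueError(f"unknown ablation {a!r}")

    def effective_weights(self) -> tuple[float, float]:
        alpha = 0.0 if "no_om" in self.ablation else self.alpha
        gamma = 0.0 if "no_fm" in self.ablation else self.gamma
        return alpha, gamma


@dataclass
class SplitData:
    """Everything one repetition trains and evaluates on."""

    network: DDINetwork
    graphs: list  # MolecularGraph per drug, aligned with network.drug_ids
    assignment: SplitAssignment
    pairs: dict  # split -> (i_idx, j_idx, labels) arrays, positives + negatives


def prepare_split_data(
    drugs: list[tuple[str, str]],
    network: DDINetwork,
    seed: int,
    neg_ratio: float = 1.0,
) -> SplitData:
    """Scaffold-split drugs, split links by endpoint, and sample negatives."""
    assignment = scaffold_split(drugs, seed=seed)
    assignment.link_split = split_links(network, assignment.drug_split)
    negatives, _short = sample_negative_links(network, assignment, neg_ratio, seed)
    by_split: dict[str, list] = {s: [] for s in ("train", "valid", "test")}
    label_of = {(i, j): y for i, j, y in network.labeled_pairs}
    for (i, j), s in assignment.link_split.items():
        by_split[s].append((i, j, label_of[(i, j)]))
    for s, negs in negatives.items():
        by_split[s].extend(negs)
    graphs = []
    smiles_of = dict(drugs)
    for d in network.drug_ids:
        g = parse_smiles(smiles_of[d])
        if g is None:
            raise ValueError(f"drug {d!r} has unparseable SMILES")
        graphs.append(g)
    pairs = {}
    for s, rows in by_split.items():
        arr = np.array(rows, dtype=np.intp).reshape(-1, 3)
        pairs[s] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return SplitData(network=network, graphs=graphs, assignment=assignment, pairs=pairs)


@dataclass
class TrainResult:
    mol_encoder: MolecularEncoder
    net_encoder: NetworkEncoder
    predictor: LinkPredictorParams
    metrics: dict  # split -> metric dict (at the selected epoch)
    loss_log: list  # per-epoch LossBreakdown dicts
    best_epoch: int


class DDIModel:
    """The full two-view model with its forward pass."""

    def __init__(self, config: ExperimentConfig, seed: int, pretrained: MolecularEncoder | None):
        if pretrained is not None and "no_pretrain" not in config.ablation:
            self.mol = MolecularEncoder(
                hidden_dim=pretrained.hidden_dim,
                num_layers=pretrained.num_layers,
                seed=seed,
            )
            self.mol.load_arrays(pretrained.copy_arrays())
        else:
            self.mol = MolecularEncoder(
                hidden_dim=config.emb_dim, num_layers=config.mol_layers, seed=seed
            )
        dim = self.mol.hidden_dim
        self.net = NetworkEncoder(hidden_dim=dim, num_layers=config.intra_layers, seed=seed)
        self.pred = LinkPredictorParams.init(dim=dim, seed=seed)
        self.config = config

    def trainable(self):
        params = self.net.tensors() + self.pred.tensors()
        if not self.config.freeze_pretrained:
            params += self.mol.tensors()
        return params

    def forward(self, data: SplitData, mol_batch: dict):
        """H, D and a scorer closure over the current weights."""
        if self.config.freeze_pretrained:
            H_np = self.mol.encode_batch(mol_batch)
            H = ad.Tensor(H_np.data if isinstance(H_np, ad.Tensor) else H_np)
        else:
            H = self.mol.encode_batch(mol_batch)
        D = encode_network(H, data.network, self.net, data.assignment.link_split)
        return H, D

    def logp_pairs(self, H, D, i_idx, j_idx):
        I = ad.mul(ad.take_rows(D, i_idx), ad.take_rows(D, j_idx))
        F = ad.mul(ad.take_rows(H, i_idx), ad.take_rows(H, j_idx))
        return main_logp(I, self.pred), aux_logp(F, self.pred)

    def snapshot(self) -> dict:
        return {
            "mol": self.mol.copy_arrays(),
            "net": self.net.copy_arrays(),
            "pred": self.pred.copy_arrays(),
        }

    def restore(self, snap: dict) -> None:
        self.mol.load_arrays(snap["mol"])
        self.net.load_arrays(snap["net"])
        self.pred.load_arrays(snap["pred"])


def _scores_for_split(model: DDIModel, data: SplitData, mol_batch: dict, split: str):
    i_idx, j_idx, y = data.pairs[split]
    H, D = model.forward(data, mol_batch)
    logp, _ = model.logp_pairs(H.detach() if isinstance(H, ad.Tensor) else H,
                               D.detach() if isinstance(D, ad.Tensor) else D,
                               i_idx, j_idx)
    return np.exp(logp.data[:, 1]), y


def train(
    config: ExperimentConfig,
    data: SplitData,
    pretrained: MolecularEncoder | None = None,
    seed: int = 0,
) -> TrainResult:
    """One full training repetition; deterministic for a given seed."""
    config.validate()
    i_tr, j_tr, y_tr = data.pairs["train"]
    if len(y_tr) == 0:
        raise ValueError("empty train split")
    alpha, gamma = config.effective_weights()
    model = DDIModel(config, seed=seed, pretrained=pretrained)
    mol_batch = model.mol.batch_constants(
        [model.mol.graph_constants(g) for g in data.graphs]
    )
    opt = Adam(model.trainable(), lr=config.learning_rate)
    best = (-np.inf, 0, model.snapshot())
    loss_log: list[dict] = []
    since_best = 0
    m = len(y_tr)
    for epoch in range(config.epochs):
        order = np.random.default_rng([seed, 0x7A1, epoch]).permutation(m)
        sums = np.zeros(4)
        for start in range(0, m, config.batch_size):
            take = order[start:start + config.batch_size]
            i_b, j_b, y_b = i_tr[take], j_tr[take], y_tr[take]
            H, D = model.forward(data, mol_batch)
            logp, logq = model.logp_pairs(H, D, i_b, j_b)
            P, Q = ad.exp(logp), ad.exp(logq)
            Ls = ad.add(cross_entropy_matrix(P, y_b), cross_entropy_matrix(Q, y_b))
            Lom = kl_matrix(P, Q)
            # feature-space matching runs over the drugs the batch touches
            touched = np.unique(np.concatenate([i_b, j_b]))
            Lfm = cmd_loss(ad.take_rows(D, touched), ad.take_rows(H, touched), K=config.K)
            loss = total_loss(Ls, Lom, Lfm, alpha=alpha, gamma=gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums += [Ls.item(), Lom.item(), Lfm.item(), loss.item()]
        breakdown = LossBreakdown(
            Ls=sums[0], Lom=sums[1], Lfm=sums[2], total=sums[3],
            alpha=alpha, gamma=gamma, K=config.K,
        )
        loss_log.append({"epoch": epoch, **breakdown.as_dict()})
        # validation-based model selection; epochs before selection_start are
        # warm-up and never eligible (an untrained model can fluke a high
        # validation score and freeze training through the patience window)
        if epoch + 1 < min(config.selection_start, config.epochs):
            continue
        can_validate = len(data.pairs["valid"][2]) > 0 and len(set(data.pairs["valid"][2])) == 2
        if can_validate:
            scores, y = _scores_for_split(model, data, mol_batch, "valid")
            val = auroc(scores, y)
        else:
            val = -loss.item()  # fall back to train loss when valid is unusable
        if val > best[0]:
            best = (val, epoch, model.snapshot())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best[0] == -np.inf:
        best = (0.0, len(loss_log) - 1, model.snapshot())
    model.restore(best[2])
    metrics = {}
    for split in ("train", "valid", "test"):
        i_s, j_s, y_s = data.pairs[split]
        if len(y_s) == 0 or len(set(y_s.tolist())) < 2:
            continue
        scores, y = _scores_for_split(model, data, mol_batch, split)
        metrics[split] = compute_metrics(scores, y, config.threshold)
    return TrainResult(
        mol_encoder=model.mol,
        net_encoder=model.net,
        predictor=model.pred,
        metrics=metrics,
        loss_log=loss_log,
        best_epoch=best[1],
    )


# -- repetition protocol ------------------------------------------------


@dataclass
class MetricReport:
    per_seed: pd.DataFrame  # rows: (seed, split, metric columns)
    aggregate: pd.DataFrame  # rows: (split, metric mean/std columns)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "MetricReport":
        per_seed = pd.DataFrame(rows)
        agg = (
            per_seed.groupby("split")[list(METRICS)]
            .agg(["mean", "std"])
            .fillna(0.0)
        )
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return cls(per_seed=per_seed, aggregate=agg.reset_index())

    def mean(self, split: str, metric: str) -> float:
        row = self.aggregate[self.aggregate["split"] == split]
        return float(row[f"{metric}_mean"].iloc[0])


def run_experiment(
    config: ExperimentConfig,
    drugs: list[tuple[str, str]],
    network: DDINetwork,
    pretrained: MolecularEncoder | None = None,
) -> tuple[MetricReport, list[TrainResult]]:
    """The multi-seed protocol: re-split, re-sample, re-train per seed."""
    config.validate()
    rows, results = [], []
    for seed in config.seeds:
        data = prepare_split_data(drugs, network, seed=seed, neg_ratio=config.neg_ratio)
        result = train(config, data, pretrained=pretrained, seed=seed)
        results.append(result)
        for split, m in result.metrics.items():
            rows.append({"seed": seed, "split": split, **m})
        logger.info("seed %d test metrics: %s", seed, result.metrics.get("test"))
    return MetricReport.from_rows(rows), results


def sweep(
    config: ExperimentConfig,
    drugs: list[tuple[str, str]],
    network: DDINetwork,
    parameter: str,
    values: list[float],
    pretrained: MolecularEncoder | None = None,
) -> pd.DataFrame:
    """Re-run the experiment for each value of ``alpha`` or ``gamma``."""
    if parameter not in ("alpha", "gamma"):
        raise ValueError("sweep parameter must be 'alpha' or 'gamma'")
    if not values:
        raise ValueError("sweep needs at least one value")
    rows = []
    for v in values:
        cfg = replace(config, **{parameter: float(v)})
        report, _ = run_experiment(cfg, drugs, network, pretrained=pretrained)
        for _, r in report.aggregate.iterrows():
            rows.append({parameter: v, **r.to_dict()})
    return pd.DataFrame(rows)


def write_loss_log(path, loss_log: list[dict]) -> None:
    """Persist the per-epoch loss record as JSON-lines."""
    with open(path, "w") as fh:
        for rec in loss_log:
            fh.write(json.dumps(rec) + "\n")
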