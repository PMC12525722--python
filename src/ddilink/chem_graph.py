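"""Molecule parsing, featurization, scaffold splitting and link sampling.

Drugs arrive as SMILES strings and are converted with RDKit into
attributed molecular graphs: each atom carries two categorical codes
(atomic-number index, chirality tag), each bond two (bond type, bond
direction). The DDI network is an undirected graph over drugs with
binary interaction labels.

Data splitting follows the scaffold protocol: drugs are grouped by
canonical Bemis-Murcko scaffold, whole groups are shuffled and assigned
greedily to train/valid/test in an 8:1:1 ratio, so no two-dimensional
structural framework ever straddles splits. Labeled links inherit the
most-held-out endpoint (test > valid > train), guaranteeing that every
test link involves a drug from an unseen scaffold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

# categorical vocabularies (minimal featurization scheme)
NUM_ATOM_TYPES = 119  # atomic numbers 1..119 -> index Z-1
MASK_ATOM_INDEX = NUM_ATOM_TYPES  # reserved token for masked atoms
NUM_CHIRALITY_TAGS = 4

_CHIRALITY_LIST = [
    Chem.rdchem.ChiralType.CHI_UNSPECIFIED,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.rdchem.ChiralType.CHI_OTHER,
]

_BOND_TYPE_LIST = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]
NUM_BOND_TYPES = len(_BOND_TYPE_LIST)

_BOND_DIR_LIST = [
    Chem.rdchem.BondDir.NONE,
    Chem.rdchem.BondDir.ENDUPRIGHT,
    Chem.rdchem.BondDir.ENDDOWNRIGHT,
]
NUM_BOND_DIRS = len(_BOND_DIR_LIST)

SPLITS = ("train", "valid", "test")


@dataclass
class MolecularGraph:
    """One drug as an attributed graph: atoms are nodes, bonds are edges.

    ``node_features[i] = (atomic_number_index, chirality_tag)``;
    ``edge_features[k] = (bond_type, bond_direction)`` for the bond
    ``edge_index[k] = (i, j)`` stored once with ``i < j`` and treated
    symmetrically.
    """

    node_features: np.ndarray  # (num_atoms, 2) int
    edge_index: np.ndarray  # (num_edges, 2) int, i < j
    edge_features: np.ndarray  # (num_edges, 2) int
    source_smiles: str = ""

    @property
    def num_atoms(self) -> int:
        return int(self.node_features.shape[0])

    @property
    def num_edges(self) -> int:
        return int(self.edge_index.shape[0])

    def validate(self) -> None:
        if self.num_atoms < 1:
            raise ValueError("molecular graph must have at least one atom")
        if self.num_edges:
            i, j = self.edge_index[:, 0], self.edge_index[:, 1]
            if np.any(i == j):
                raise ValueError("self-loop bond")
            if self.edge_index.max() >= self.num_atoms:
                raise ValueError("atom index out of range")

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 bond adjacency matrix."""
        A = np.zeros((self.num_atoms, self.num_atoms), dtype=np.float64)
        for i, j in self.edge_index:
            A[i, j] = A[j, i] = 1.0
        return A


@dataclass
class DDINetwork:
    """Drugs as nodes, known interactions as labeled undirected links."""

    drug_ids: list
    adjacency: np.ndarray  # (n, n) symmetric 0/1, zero diagonal
    labeled_pairs: list  # [(i, j, y)] with i < j, y in {0, 1}

    @property
    def n(self) -> int:
        return len(self.drug_ids)

    def validate(self) -> None:
        A = self.adjacency
        if A.shape != (self.n, self.n):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        for i, j, y in self.labeled_pairs:
            if y == 1 and A[i, j] != 1:
                raise ValueError(f"positive pair ({i},{j}) missing from adjacency")
            if y == 0 and A[i, j] != 0:
                raise ValueError(f"negative pair ({i},{j}) present in adjacency")

    @classmethod
    def from_pairs(cls, drug_ids: Sequence, pairs: Iterable[tuple]) -> "DDINetwork":
        """Build from (id_a, id_b[, label]) records; a missing label means 1."""
        index = {d: k for k, d in enumerate(drug_ids)}
        n = len(drug_ids)
        A = np.zeros((n, n), dtype=np.int8)
        labeled = []
        seen = set()
        for rec in pairs:
            a, b = rec[0], rec[1]
            y = int(rec[2]) if len(rec) > 2 else 1
            if a not in index or b not in index:
                raise KeyError(f"pair ({a},{b}) references unknown drug")
            i, j = sorted((index[a], index[b]))
            if i == j or (i, j) in seen:
                continue
            seen.add((i, j))
            labeled.append((i, j, y))
            if y == 1:
                A[i, j] = A[j, i] = 1
        return cls(list(drug_ids), A, labeled)


@dataclass
class SplitAssignment:
    """Per-drug and per-link split labels for one seed."""

    drug_split: dict  # drug_id -> 'train' | 'valid' | 'test'
    link_split: dict = field(default_factory=dict)  # (i, j) -> split
    seed: int = 0
    empty_splits: tuple = ()  # names of splits left empty (too few groups)


def parse_smiles(smiles: str) -> Optional[MolecularGraph]:
    """Convert one SMILES string to a :class:`MolecularGraph`.

    Returns ``None`` for unparseable input so callers can drop the record.
    """
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    nodes = np.array(
        [
            [atom.GetAtomicNum() - 1, _CHIRALITY_LIST.index(atom.GetChiralTag())
             if atom.GetChiralTag() in _CHIRALITY_LIST else 0]
            for atom in mol.GetAtoms()
        ],
        dtype=np.int64,
    ).reshape(-1, 2)
    edges, feats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bt = _BOND_TYPE_LIST.index(bond.GetBondType()) if bond.GetBondType() in _BOND_TYPE_LIST else 0
        bd = _BOND_DIR_LIST.index(bond.GetBondDir()) if bond.GetBondDir() in _BOND_DIR_LIST else 0
        edges.append(sorted((i, j)))
        feats.append([bt, bd])
    g = MolecularGraph(
        node_features=nodes,
        edge_index=np.array(edges, dtype=np.int64).reshape(-1, 2),
        edge_features=np.array(feats, dtype=np.int64).reshape(-1, 2),
        source_smiles=smiles,
    )
    g.validate()
    return g


def filter_parseable(records: Iterable[tuple]) -> tuple[list, list]:
    """Split (id, smiles) records into (kept records, dropped ids), order kept."""
    kept, dropped = [], []
    for drug_id, smiles in records:
        if parse_smiles(smiles) is None:
            dropped.append(drug_id)
        else:
            kept.append((drug_id, smiles))
    if dropped:
        logger.info("dropped %d unparseable records: %s", len(dropped), dropped[:10])
    return kept, dropped


def bemis_murcko_scaffold(smiles: str) -> Optional[str]:
    """Canonical Bemis-Murcko scaffold SMILES; '' for acyclic molecules;
    ``None`` for unparseable input."""
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        return None
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(
    drugs: Sequence[tuple],
    ratios: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Group drugs by Bemis-Murcko scaffold and assign whole groups to splits.

    Groups are shuffled with ``seed`` and filled greedily: train until it
    holds at least ``ratios[0]`` of the drugs, then valid until
    ``ratios[1]``, remainder to test. Whole scaffold groups are never split.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    groups: dict[str, list] = {}
    for drug_id, smiles in drugs:
        scaf = bemis_murcko_scaffold(smiles)
        if scaf is None:
            raise ValueError(f"drug {drug_id!r} has unparseable SMILES")
        groups.setdefault(scaf, []).append(drug_id)
    keys = sorted(groups)
    rng = np.random.default_rng([seed, 0x5CAF])
    order = rng.permutation(len(keys))
    n = len(drugs)
    n_train, n_valid = ratios[0] * n, ratios[1] * n
    drug_split: dict = {}
    counts = {"train": 0, "valid": 0, "test": 0}
    for k in order:
        members = groups[keys[k]]
        if counts["train"] < n_train:
            split = "train"
        elif counts["valid"] < n_valid:
            split = "valid"
        else:
            split = "test"
        for d in members:
            drug_split[d] = split
        counts[split] += len(members)
    empty = tuple(s for s in SPLITS if counts[s] == 0)
    if empty:
        logger.warning("splits left empty (too few scaffold groups): %s", empty)
    return SplitAssignment(drug_split=drug_split, seed=seed, empty_splits=empty)


def split_links(network: DDINetwork, drug_split: dict) -> dict:
    """Assign each labeled pair the most-held-out endpoint's split.

    A link is ``test`` if either endpoint drug is in the test split, else
    ``valid`` if either endpoint is in valid, else ``train`` — so test
    links always involve a drug from an unseen scaffold.
    """
    rank = {"train": 0, "valid": 1, "test": 2}
    link_split = {}
    for i, j, _y in network.labeled_pairs:
        for k in (i, j):
            if network.drug_ids[k] not in drug_split:
                raise KeyError(f"drug {network.drug_ids[k]!r} missing from drug split")
        si = drug_split[network.drug_ids[i]]
        sj = drug_split[network.drug_ids[j]]
        link_split[(i, j)] = si if rank[si] >= rank[sj] else sj
    return link_split


def _eligible_split(si: str, sj: str) -> str:
    rank = {"train": 0, "valid": 1, "test": 2}
    return si if rank[si] >= rank[sj] else sj


def sample_negative_links(
    network: DDINetwork,
    assignment: SplitAssignment,
    ratio: float = 1.0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Sample non-interacting drug pairs as negatives, per split.

    For each split, ``round(ratio * positives)`` unordered pairs are drawn
    uniformly from pairs that (a) are not adjacent and not already labeled,
    and (b) would belong to that split under the endpoint rule — so each
    split's negatives depend only on that split's own drugs and links.

    Returns ``(negatives, shortfall)`` where ``negatives[split]`` is a list
    of ``(i, j, 0)`` and ``shortfall[split]`` counts negatives that could
    not be drawn (0 when enough non-edges exist).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    link_split = assignment.link_split or split_links(network, assignment.drug_split)
    label_of = {(i, j): y for i, j, y in network.labeled_pairs}
    pos_counts = {s: 0 for s in SPLITS}
    for (i, j), s in link_split.items():
        if label_of[(i, j)] == 1:
            pos_counts[s] += 1
    labeled = set(label_of)
    drug_of = [assignment.drug_split[d] for d in network.drug_ids]
    n = network.n
    candidates = {s: [] for s in SPLITS}
    for i in range(n):
        for j in range(i + 1, n):
            if network.adjacency[i, j] or (i, j) in labeled:
                continue
            candidates[_eligible_split(drug_of[i], drug_of[j])].append((i, j))
    negatives, shortfall = {}, {}
    for k, s in enumerate(SPLITS):
        want = int(round(ratio * pos_counts[s]))
        pool = candidates[s]
        rng = np.random.default_rng([seed, 0x9E6, k])
        take = min(want, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False) if pool else []
        negatives[s] = [(pool[t][0], pool[t][1], 0) for t in sorted(idx)]
        shortfall[s] = want - take
        if shortfall[s]:
            logger.warning("split %s: %d negatives short of target", s, shortfall[s])
    return negatives, shortfall
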