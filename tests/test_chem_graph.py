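"""Molecule parsing, scaffolds, splitting and negative sampling."""

import numpy as np
import pytest
from rdkit import Chem

from ddilink.chem_graph import (
    DDINetwork,
    bemis_murcko_scaffold,
    filter_parseable,
    parse_smiles,
    sample_negative_links,
    scaffold_split,
    split_links,
)


class TestParseSmiles:
    @pytest.mark.parametrize(
        "smiles,n_atoms,n_edges",
        [("C", 1, 0), ("CCO", 3, 2), ("c1ccccc1", 6, 6), ("C#N", 2, 1)],
    )
    def test_counts_match_toolkit(self, smiles, n_atoms, n_edges):
        g = parse_smiles(smiles)
        mol = Chem.MolFromSmiles(smiles)
        assert g.num_atoms == mol.GetNumAtoms() == n_atoms
        assert g.num_edges == mol.GetNumBonds() == n_edges

    def test_invalid_smiles_returns_none(self):
        assert parse_smiles("not_a_smiles") is None
        assert parse_smiles("") is None

    def test_atom_features_are_atomic_number_index(self):
        g = parse_smiles("CO")
        assert set(g.node_features[:, 0]) == {5, 7}  # C -> Z-1 = 5, O -> 7

    def test_no_self_loops_and_indices_in_range(self):
        g = parse_smiles("CC1=CC(=O)C=CC1=O")
        i, j = g.edge_index[:, 0], g.edge_index[:, 1]
        assert np.all(i != j)
        assert g.edge_index.max() < g.num_atoms

    def test_roundtrip_isomorphic_under_atom_reordering(self):
        # same molecule written from different starting atoms
        a, b = parse_smiles("CCO"), parse_smiles("OCC")
        assert sorted(a.node_features[:, 0]) == sorted(b.node_features[:, 0])
        assert a.num_edges == b.num_edges
        assert sorted(map(tuple, a.edge_features.tolist())) == sorted(
            map(tuple, b.edge_features.tolist())
        )


class TestFilterParseable:
    def test_mixed_records(self):
        kept, dropped = filter_parseable([("d1", "CCO"), ("d2", "%%")])
        assert [d for d, _ in kept] == ["d1"]
        assert dropped == ["d2"]

    def test_all_valid_and_all_invalid(self):
        kept, dropped = filter_parseable([("a", "C"), ("b", "CC")])
        assert dropped == [] and len(kept) == 2
        kept, dropped = filter_parseable([("a", "("), ("b", ")")])
        assert kept == [] and dropped == ["a", "b"]


class TestScaffold:
    def test_ring_molecule_is_its_own_scaffold(self):
        assert bemis_murcko_scaffold("c1ccccc1") == "c1ccccc1"

    def test_acyclic_maps_to_empty(self):
        assert bemis_murcko_scaffold("CCO") == ""

    def test_side_chains_are_stripped(self):
        assert bemis_murcko_scaffold("CCc1ccccc1") == bemis_murcko_scaffold("c1ccccc1")

    def test_unparseable_gives_none(self):
        assert bemis_murcko_scaffold("][") is None


class TestScaffoldSplit:
    def test_singleton_groups_hit_exact_ratio(self):
        # ten structurally distinct ring systems -> ten one-drug groups
        drugs = [
            ("d0", "c1ccccc1"), ("d1", "c1ccncc1"), ("d2", "c1cncnc1"),
            ("d3", "C1CCCCC1"), ("d4", "C1CCCC1"), ("d5", "c1ccc2ccccc2c1"),
            ("d6", "C1CCOCC1"), ("d7", "c1cnccn1"), ("d8", "C1CCCCCC1"),
            ("d9", "c1cc[nH]c1"),
        ]
        a = scaffold_split(drugs, seed=3)
        from collections import Counter

        counts = Counter(a.drug_split.values())
        assert (counts["train"], counts["valid"], counts["test"]) == (8, 1, 1)

    def test_single_scaffold_group_is_atomic(self):
        drugs = [(f"d{i}", "CCc1ccccc1") for i in range(10)]
        a = scaffold_split(drugs, seed=0)
        assert set(a.drug_split.values()) == {"train"}
        assert set(a.empty_splits) == {"valid", "test"}

    def test_deterministic_per_seed(self):
        drugs = [(f"d{i}", s) for i, s in enumerate(["c1ccccc1", "CCO", "C1CCCCC1"] * 5)]
        assert scaffold_split(drugs, seed=5).drug_split == scaffold_split(drugs, seed=5).drug_split

    @pytest.mark.parametrize("seed", range(10))
    def test_no_scaffold_straddles_and_partition_complete(self, seed, toy_benchmark):
        drugs, _, _ = toy_benchmark
        a = scaffold_split(drugs, seed=seed)
        assert set(a.drug_split) == {d for d, _ in drugs}
        by_scaffold = {}
        for d, s in drugs:
            by_scaffold.setdefault(bemis_murcko_scaffold(s), set()).add(a.drug_split[d])
        assert all(len(splits) == 1 for splits in by_scaffold.values())


class TestSplitLinks:
    def _network(self):
        ids = list("abcdef")
        pairs = [(i, j) for k, i in enumerate(ids) for j in ids[k + 1:]]
        return DDINetwork.from_pairs(ids, pairs)

    def test_endpoint_rule(self):
        net = DDINetwork.from_pairs(["a", "b", "c"], [("a", "b"), ("a", "c")])
        ls = split_links(net, {"a": "train", "b": "train", "c": "test"})
        assert ls[(0, 1)] == "train"
        assert ls[(0, 2)] == "test"

    def test_exhaustive_pairs_match_bruteforce_rule(self):
        net = self._network()
        dsplit = dict(zip("abcdef", ["train", "train", "valid", "train", "test", "valid"]))
        ls = split_links(net, dsplit)
        rank = {"train": 0, "valid": 1, "test": 2}
        for i, j, _ in net.labeled_pairs:
            si, sj = dsplit[net.drug_ids[i]], dsplit[net.drug_ids[j]]
            assert ls[(i, j)] == max(si, sj, key=rank.get)
        # partition is exhaustive and disjoint over labeled pairs
        assert set(ls) == {(i, j) for i, j, _ in net.labeled_pairs}

    def test_missing_drug_errors_with_name(self):
        net = DDINetwork.from_pairs(["a", "b"], [("a", "b")])
        with pytest.raises(KeyError, match="b"):
            split_links(net, {"a": "train"})


class TestNegativeSampling:
    def _assignment(self, net, drug_split):
        from ddilink.chem_graph import SplitAssignment

        a = SplitAssignment(drug_split=drug_split)
        a.link_split = split_links(net, drug_split)
        return a

    def test_complete_graph_reports_shortfall(self):
        ids = ["a", "b", "c"]
        net = DDINetwork.from_pairs(ids, [("a", "b"), ("a", "c"), ("b", "c")])
        a = self._assignment(net, {d: "train" for d in ids})
        negs, short = sample_negative_links(net, a, ratio=1.0, seed=0)
        assert negs["train"] == []
        assert short["train"] == 3

    def test_single_positive_yields_single_distinct_negative(self):
        ids = ["a", "b", "c", "d"]
        net = DDINetwork.from_pairs(ids, [("a", "b")])
        a = self._assignment(net, {d: "train" for d in ids})
        negs, short = sample_negative_links(net, a, ratio=1.0, seed=1)
        assert len(negs["train"]) == 1 and short["train"] == 0
        assert negs["train"][0][:2] != (0, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_negatives_disjoint_from_positives(self, seed, toy_benchmark):
        drugs, net, _ = toy_benchmark
        a = scaffold_split(drugs, seed=seed)
        a.link_split = split_links(net, a.drug_split)
        negs, _ = sample_negative_links(net, a, ratio=1.0, seed=seed)
        pos = {(i, j) for i, j, y in net.labeled_pairs if y == 1}
        for s, lst in negs.items():
            assert all((i, j) not in pos for i, j, _ in lst)
            assert all(net.adjacency[i, j] == 0 for i, j, _ in lst)

    def test_negatives_respect_split_eligibility(self, toy_benchmark):
        drugs, net, _ = toy_benchmark
        a = scaffold_split(drugs, seed=2)
        a.link_split = split_links(net, a.drug_split)
        negs, _ = sample_negative_links(net, a, ratio=1.0, seed=2)
        rank = {"train": 0, "valid": 1, "test": 2}
        for s, lst in negs.items():
            for i, j, _ in lst:
                si = a.drug_split[net.drug_ids[i]]
                sj = a.drug_split[net.drug_ids[j]]
                assert max(si, sj, key=rank.get) == s


def test_network_invariants_validate():
    net = DDINetwork.from_pairs(["a", "b", "c"], [("a", "b", 1), ("a", "c", 0)])
    net.validate()
    assert net.adjacency[0, 1] == 1 and net.adjacency[0, 2] == 0
    assert (0, 2, 0) in net.labeled_pairs
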