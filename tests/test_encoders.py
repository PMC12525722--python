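"""GCN propagation arithmetic against dense oracles."""

import numpy as np
import pytest

from ddilink.autodiff import Tensor
from ddilink.chem_graph import MolecularGraph, parse_smiles
from ddilink.encoders import (
    MolecularEncoder,
    NetworkEncoder,
    encode_molecule,
    encode_network,
    gcn_layer,
    load_checkpoint,
    normalize_adjacency,
    save_checkpoint,
)
from ddilink.chem_graph import DDINetwork


def dense_normalized(A):
    """Independent closed form: Deg^{-1/2} (A+I) Deg^{-1/2} via explicit diag."""
    Ahat = A + np.eye(len(A))
    D = np.diag(Ahat.sum(axis=1))
    Dinv = np.linalg.inv(np.sqrt(D))
    return Dinv @ Ahat @ Dinv


class TestNormalizeAdjacency:
    def test_isolated_node(self):
        np.testing.assert_allclose(normalize_adjacency([[0.0]]), [[1.0]])

    def test_zero_matrix_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_two_node_edge(self):
        np.testing.assert_allclose(
            normalize_adjacency([[0, 1], [1, 0]]), [[0.5, 0.5], [0.5, 0.5]]
        )

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            normalize_adjacency([[0, 1], [0, 0]])

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_closed_form_on_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(1, 11))
        A = rng.integers(0, 2, (n, n)).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        np.testing.assert_allclose(normalize_adjacency(A), dense_normalized(A), atol=1e-12)


class TestGcnLayer:
    def test_identity_propagation(self):
        X = np.arange(6.0).reshape(3, 2)
        np.testing.assert_allclose(gcn_layer(np.eye(3), X, np.eye(2), activate=False), X)

    def test_relu_clamps_negatives(self):
        X = np.array([[-1.0, 2.0]])
        out = gcn_layer(np.eye(1), X, np.eye(2), activate=True)
        np.testing.assert_allclose(out, [[0.0, 2.0]])

    def test_path_graph_matches_dense_oracle(self, rng):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        S = normalize_adjacency(A)
        X, W = rng.normal(size=(3, 4)), rng.normal(size=(4, 4))
        np.testing.assert_allclose(
            gcn_layer(S, X, W, activate=True), np.maximum(S @ X @ W, 0), atol=1e-12
        )


def oracle_encode_molecule(g: MolecularGraph, enc: MolecularEncoder) -> np.ndarray:
    """Layer-by-layer dense replication of the molecular encoder."""
    p = {k: v.data for k, v in enc.params.items()}
    S = dense_normalized(g.adjacency())
    X = p["atom_emb"][g.node_features[:, 0]] + p["chir_emb"][g.node_features[:, 1]]
    for l in range(enc.num_layers):
        B = np.zeros((g.num_atoms, enc.hidden_dim))
        for (i, j), (bt, bd) in zip(g.edge_index, g.edge_features):
            B[i] += S[i, j] * (p[f"bond_type{l}"][bt] + p[f"bond_dir{l}"][bd])
            B[j] += S[j, i] * (p[f"bond_type{l}"][bt] + p[f"bond_dir{l}"][bd])
        X = S @ X @ p[f"W{l}"] + B
        mu = X.mean(axis=1, keepdims=True)
        var = ((X - mu) ** 2).mean(axis=1, keepdims=True)
        X = (X - mu) / np.sqrt(var + enc.LN_EPS) * p[f"ln_gain{l}"] + p[f"ln_bias{l}"]
        if l < enc.num_layers - 1:
            X = np.maximum(X, 0)
    return X.mean(axis=0)


class TestMolecularEncoder:
    def test_default_embedding_length_is_300(self):
        enc = MolecularEncoder(seed=0)
        v = encode_molecule(parse_smiles("CCO"), enc)
        assert v.shape == (300,)

    def test_single_atom_output_equals_its_node_state(self):
        enc = MolecularEncoder(hidden_dim=16, num_layers=3, seed=1)
        g = parse_smiles("C")
        batch = enc.batch_constants([enc.graph_constants(g)])
        node = enc.node_states(batch).data[0, 0]
        np.testing.assert_allclose(encode_molecule(g, enc), node)

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccncc1", "CC(C)CC", "C1CCCCC1O"])
    def test_matches_dense_oracle(self, smiles):
        enc = MolecularEncoder(hidden_dim=12, num_layers=5, seed=2)
        g = parse_smiles(smiles)
        np.testing.assert_allclose(
            encode_molecule(g, enc), oracle_encode_molecule(g, enc), atol=1e-10
        )

    def test_permutation_invariance(self):
        enc = MolecularEncoder(hidden_dim=16, num_layers=5, seed=3)
        g = parse_smiles("CCO")
        perm = [2, 0, 1]
        inv = np.argsort(perm)
        relabeled = MolecularGraph(
            node_features=g.node_features[perm],
            edge_index=np.sort(inv[g.edge_index], axis=1),
            edge_features=g.edge_features.copy(),
            source_smiles=g.source_smiles,
        )
        np.testing.assert_allclose(
            encode_molecule(g, enc), encode_molecule(relabeled, enc), atol=1e-9
        )

    def test_deterministic_in_eval(self):
        enc = MolecularEncoder(hidden_dim=8, num_layers=2, seed=4)
        g = parse_smiles("c1ccccc1CC")
        np.testing.assert_array_equal(encode_molecule(g, enc), encode_molecule(g, enc))

    def test_empty_graph_rejected(self):
        enc = MolecularEncoder(hidden_dim=8, num_layers=2, seed=0)
        empty = MolecularGraph(
            node_features=np.zeros((0, 2), dtype=int),
            edge_index=np.zeros((0, 2), dtype=int),
            edge_features=np.zeros((0, 2), dtype=int),
        )
        with pytest.raises(ValueError):
            encode_molecule(empty, enc)


class TestNetworkEncoder:
    def _toy(self, n=4, dim=6, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"d{i}" for i in range(n)]
        pairs = [("d0", "d1"), ("d1", "d2"), ("d2", "d3")]
        net = DDINetwork.from_pairs(ids, pairs)
        H = rng.normal(size=(n, dim))
        enc = NetworkEncoder(hidden_dim=dim, num_layers=2, seed=seed)
        return net, H, enc

    def test_zero_links_reduces_to_mlp_form(self):
        ids = ["a", "b", "c"]
        net = DDINetwork(ids, np.zeros((3, 3), dtype=np.int8), [])
        rng = np.random.default_rng(0)
        H = rng.normal(size=(3, 5))
        enc = NetworkEncoder(hidden_dim=5, num_layers=2, seed=1)
        W0, W1 = enc.params["W0"].data, enc.params["W1"].data
        expect = np.maximum(np.maximum(H @ W0, 0) @ W1, 0)
        np.testing.assert_allclose(encode_network(H, net, enc).data, expect, atol=1e-12)

    def test_matches_layer_by_layer_dense_oracle(self):
        net, H, enc = self._toy()
        S = dense_normalized(net.adjacency.astype(float))
        X = H
        for l in range(2):
            X = np.maximum(S @ X @ enc.params[f"W{l}"].data, 0)
        np.testing.assert_allclose(encode_network(H, net, enc).data, X, atol=1e-12)

    def test_identity_weights_no_activation_is_adjacency_smoothing(self):
        net, H, _ = self._toy()
        S = normalize_adjacency(net.adjacency.astype(float))
        out = gcn_layer(S, gcn_layer(S, H, np.eye(6), activate=False), np.eye(6), activate=False)
        np.testing.assert_allclose(out, S @ S @ H, atol=1e-12)

    def test_output_shape_and_dimension_check(self):
        net, H, enc = self._toy()
        assert encode_network(H, net, enc).data.shape == (4, 6)
        with pytest.raises(ValueError):
            encode_network(H[:, :3], net, enc)

    def test_train_split_links_only(self):
        net, H, enc = self._toy()
        link_split = {(0, 1): "train", (1, 2): "test", (2, 3): "valid"}
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        S = dense_normalized(A)
        X = H
        for l in range(2):
            X = np.maximum(S @ X @ enc.params[f"W{l}"].data, 0)
        np.testing.assert_allclose(
            encode_network(H, net, enc, link_split).data, X, atol=1e-12
        )


def test_checkpoint_roundtrip(tmp_path):
    enc = MolecularEncoder(hidden_dim=8, num_layers=2, seed=9)
    path = tmp_path / "enc.npz"
    save_checkpoint(path, enc, {"strategy": "masking_node"})
    loaded, meta = load_checkpoint(path)
    assert meta["strategy"] == "masking_node"
    assert meta["vocab"]["atom_types"] == 119
    g = parse_smiles("CCO")
    np.testing.assert_array_equal(encode_molecule(g, enc), encode_molecule(g, loaded))
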