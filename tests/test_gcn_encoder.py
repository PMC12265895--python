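import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndlsdti.chem_graph import MolecularGraph, parse_smiles
from ndlsdti.gcn_encoder import (EncoderConfig, GCNEncoder, encode_entity,
                                 gcn_layer, mean_readout, normalize_adjacency,
                                 train_encoders)
from ndlsdti.prot_graph import encode_sequence
from ndlsdti.synthetic import PlantedWorld, generate_world

from helpers import random_connected_adjacency


class TestNormalizeAdjacency:
    def test_two_nodes_one_edge_symmetric(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalize_adjacency(A, True, 0.5), 0.5)

    def test_path_of_three_analytic(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        ahat = normalize_adjacency(A, True, 0.5)
        assert ahat[0, 1] == pytest.approx(1 / np.sqrt(6))
        assert np.allclose(ahat, ahat.T)

    @given(st.integers(2, 12), st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_r_one_rows_sum_to_one(self, n, seed):
        A = random_connected_adjacency(n, np.random.default_rng(seed))
        ahat = normalize_adjacency(A, True, 1.0)
        assert np.allclose(ahat.sum(axis=1), 1.0)

    def test_r_half_spectral_radius_at_most_one(self, rng):
        A = random_connected_adjacency(10, rng)
        ahat = normalize_adjacency(A, True, 0.5)
        assert np.max(np.abs(np.linalg.eigvalsh(ahat))) <= 1 + 1e-12

    def test_sparse_matches_dense(self, rng):
        from scipy import sparse

        A = random_connected_adjacency(8, rng)
        dense = normalize_adjacency(A, True, 0.5)
        sp = normalize_adjacency(sparse.csr_matrix(A), True, 0.5)
        assert np.allclose(sp.toarray(), dense)

    def test_isolated_node_without_loops_errors(self):
        A = np.zeros((2, 2))
        with pytest.raises(ValueError, match="zero-degree"):
            normalize_adjacency(A, False, 0.5)


class TestLayerAndReadout:
    def test_identity_weight_identity_activation(self):
        A = np.array([[0.5, 0.5], [0.5, 0.5]])
        X = np.eye(2)
        assert np.allclose(gcn_layer(X, A, np.eye(2), "identity"), A @ X)

    def test_zero_input_relu(self):
        A = np.eye(3)
        out = gcn_layer(np.zeros((3, 2)), A, np.ones((2, 4)), "relu")
        assert np.all(out == 0)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            gcn_layer(np.ones((2, 3)), np.eye(2), np.ones((4, 5)))

    def test_mean_readout_cases(self):
        assert np.allclose(mean_readout(np.array([[0.0, 2.0], [2.0, 0.0]])), [1, 1])
        single = np.array([[3.0, -1.0]])
        assert np.allclose(mean_readout(single), single[0])
        with pytest.raises(ValueError):
            mean_readout(np.zeros((0, 4)))


def _permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    return MolecularGraph(g.drug_id, g.atom_features[perm],
                          g.adjacency[np.ix_(perm, perm)], g.smiles)


class TestEncodeEntity:
    def test_output_width_is_config_dim(self):
        cfg = EncoderConfig(output_dim=128)
        enc = GCNEncoder.random(cfg, input_dim=5, seed=0)
        z = encode_entity(parse_smiles("CCO", "d"), enc)
        assert z.shape == (128,)

    def test_permutation_invariance(self, rng):
        cfg = EncoderConfig(output_dim=16, hidden_dim=8)
        enc = GCNEncoder.random(cfg, input_dim=5, seed=3)
        g = parse_smiles("CC(=O)NCCc1ccccc1", "d")
        z = encode_entity(g, enc)
        for _ in range(20):
            perm = rng.permutation(g.n_atoms)
            gp = _permute_graph(g, perm)
            gp.drug_id = f"perm{_}"
            assert np.allclose(encode_entity(gp, enc), z, atol=1e-10)

    def test_single_atom_is_input_times_weight(self):
        cfg = EncoderConfig(num_layers=1, output_dim=4, activation="identity")
        enc = GCNEncoder.random(cfg, input_dim=5, seed=0)
        g = parse_smiles("C", "methane")
        expected = np.asarray(g.atom_features, float) @ enc.weights[0]
        assert np.allclose(encode_entity(g, enc), expected[0])

    def test_identity_stack_equals_matrix_power_mean(self, rng):
        """sigma=identity, W=I stacked k times == mean of rows of A_hat^k X."""
        k = 3
        cfg = EncoderConfig(num_layers=k, hidden_dim=5, output_dim=5, activation="identity")
        enc = GCNEncoder.random(cfg, input_dim=5, seed=0)
        enc.weights = [np.eye(5) for _ in range(k)]
        g = parse_smiles("OCC(O)CO", "d")
        ahat = normalize_adjacency(np.asarray(g.adjacency, float), True, 0.5)
        oracle = np.linalg.matrix_power(ahat, k) @ np.asarray(g.atom_features, float)
        assert np.allclose(encode_entity(g, enc), oracle.mean(axis=0), atol=1e-10)

    def test_sequence_graph_uses_embedding_table(self):
        cfg = EncoderConfig(output_dim=8, hidden_dim=4)
        enc = GCNEncoder.random(cfg, input_dim=cfg.residue_embed_dim,
                                embed_vocab=cfg.residue_vocab, seed=1)
        z = encode_entity(encode_sequence("ACDEFGHIK", target_id="t"), enc)
        assert z.shape == (8,) and np.all(np.isfinite(z))


@pytest.fixture(scope="module")
def small_training_setup():
    world = PlantedWorld(n_drugs=16, n_targets=12, n_clusters=4,
                         p_in=0.9, p_out=0.05, seed=21)
    drugs, targets, pairs = generate_world(world)
    from ndlsdti.chem_graph import parse_smiles_table
    from ndlsdti.prot_graph import encode_sequence_table
    dg = parse_smiles_table(list(zip(drugs["drug_id"], drugs["smiles"])))
    tg = encode_sequence_table(list(zip(targets["target_id"], targets["sequence"])))
    triples = list(pairs[["drug_id", "target_id", "label"]]
                   .itertuples(index=False, name=None))
    return triples, dg, tg


class TestTraining:
    def test_loss_decreases_on_toy_set(self, small_training_setup):
        triples, dg, tg = small_training_setup
        cfg = EncoderConfig(epochs=25, hidden_dim=16, output_dim=16,
                            val_fraction=0.0, seed=5)
        trained = train_encoders(triples, dg, tg, cfg)
        losses = [h["loss"] for h in trained.history]
        assert losses[-1] < losses[0]

    def test_same_seed_bitwise_identical(self, small_training_setup):
        triples, dg, tg = small_training_setup
        cfg = EncoderConfig(epochs=5, hidden_dim=8, output_dim=8, seed=9)
        w1 = train_encoders(triples, dg, tg, cfg).drug_encoder.weights
        w2 = train_encoders(triples, dg, tg, cfg).drug_encoder.weights
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_single_class_labels_rejected(self, small_training_setup):
        triples, dg, tg = small_training_setup
        only_pos = [t for t in triples if t[2] == 1]
        with pytest.raises(ValueError, match="both classes"):
            train_encoders(only_pos, dg, tg, EncoderConfig(epochs=1))

    def test_trained_head_beats_chance_on_heldout(self, small_training_setup):
        from sklearn.metrics import roc_auc_score

        triples, dg, tg = small_training_setup
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(triples))
        cut = int(0.8 * len(idx))
        train = [triples[i] for i in idx[:cut]]
        test = [triples[i] for i in idx[cut:]]
        cfg = EncoderConfig(epochs=30, hidden_dim=16, output_dim=16, seed=2)
        tr = train_encoders(train, dg, tg, cfg)
        zd = {d: tr.drug_encoder.embed(dg[d]) for d in dg}
        zt = {t: tr.target_encoder.embed(tg[t]) for t in tg}
        # rank held-out pairs by embedding dot product (head was discarded)
        scores = [float(zd[d] @ zt[t]) for d, t, _ in test]
        labels = [y for _, _, y in test]
        assert roc_auc_score(labels, scores) > 0.5
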