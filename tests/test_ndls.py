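import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ndlsdti.gcn_encoder import normalize_adjacency
from ndlsdti.hetgraph import assemble_hetgraph
from ndlsdti.ndls import (NdlsConfig, compute_all_lsi, compute_lsi,
                          fixed_depth_smooth, influence_row, ndls_profile,
                          ndls_smooth, propagation_matrix, stationary_influence)

from helpers import influence_oracle, lsi_oracle, random_connected_adjacency


def _ahat_and_degrees(A: np.ndarray, r: float = 0.5):
    At = A + np.eye(A.shape[0])
    return normalize_adjacency(At, self_loops=False, r=r), At.sum(axis=1)


def _two_node():
    return _ahat_and_degrees(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestPropagationMatrix:
    def _graph(self, dd=(), dt=()):
        d = pd.DataFrame(np.ones((3, 2)), index=["d1", "d2", "d3"])
        t = pd.DataFrame(np.ones((1, 2)), index=["t1"])
        return assemble_hetgraph(d, t, dd_edges=dd, dt_edges=dt)

    def test_isolated_node_self_loop_only(self):
        ahat = propagation_matrix(self._graph()).toarray()
        assert np.allclose(ahat, np.eye(4))

    def test_two_connected_nodes_half(self):
        ahat = propagation_matrix(self._graph(dd=[("d1", "d2", 0.8)])).toarray()
        assert np.allclose(ahat[:2, :2], 0.5)

    def test_disconnected_components_block_diagonal(self):
        ahat = propagation_matrix(
            self._graph(dd=[("d1", "d2", 0.8)], dt=[("d3", "t1")])).toarray()
        assert np.all(ahat[:2, 2:] == 0) and np.all(ahat[2:, :2] == 0)


class TestInfluenceRow:
    def test_k0_is_indicator(self, rng):
        A, _ = _ahat_and_degrees(random_connected_adjacency(6, rng))
        assert np.array_equal(influence_row(A, 2, 0), np.eye(6)[2])

    def test_k1_is_matrix_row(self, rng):
        A, _ = _ahat_and_degrees(random_connected_adjacency(6, rng))
        assert np.allclose(influence_row(A, 3, 1), A[3])

    def test_k3_matches_dense_power_oracle(self, rng):
        A, _ = _ahat_and_degrees(random_connected_adjacency(5, rng))
        assert np.allclose(influence_row(A, 1, 3), influence_oracle(A, 1, 3), atol=1e-12)

    def test_out_of_range_k_errors(self):
        A, _ = _two_node()
        with pytest.raises(ValueError, match="out of range"):
            influence_row(A, 0, 7, k_max=5)


class TestStationaryInfluence:
    def test_two_node_single_edge_all_half(self):
        A, deg = _two_node()
        assert np.allclose(stationary_influence(A, deg), 0.5)

    def test_row_scaled_by_sqrt_degree_is_constant(self, rng):
        A, deg = _ahat_and_degrees(random_connected_adjacency(9, rng))
        I = stationary_influence(A, deg)
        scaled = I / np.sqrt(deg)[None, :]
        assert np.allclose(scaled, scaled[:, :1])

    def test_power_iteration_converges_to_closed_form(self, rng):
        A, deg = _ahat_and_degrees(random_connected_adjacency(10, rng))
        I = stationary_influence(A, deg)
        M = np.linalg.matrix_power(A, 200)
        assert np.max(np.abs(M - I)) < 1e-8

    def test_zero_across_components(self):
        A = np.array([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], float)
        Ah, deg = _ahat_and_degrees(A)
        I = stationary_influence(Ah, deg)
        assert np.all(I[:2, 2:] == 0) and np.all(I[2:, :2] == 0)


class TestLSI:
    def test_two_node_graph_k_equals_one(self):
        A, deg = _two_node()
        I = stationary_influence(A, deg)
        # at k=0 the distance is ||e_0 - (0.5, 0.5)|| = sqrt(0.5); at k=1 it is 0
        assert compute_lsi(A, I, 0, epsilon=0.1) == 1

    def test_complete_k3_with_loops_k_equals_one(self):
        A = np.ones((3, 3)) - np.eye(3)
        Ah, deg = _ahat_and_degrees(A)
        I = stationary_influence(Ah, deg)
        for eps in (0.01, 0.2, 0.79):
            assert compute_lsi(Ah, I, 0, epsilon=eps) == 1

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            A, deg = _ahat_and_degrees(random_connected_adjacency(n, rng))
            I = stationary_influence(A, deg)
            for i in (0, n // 2):
                for eps in (0.2, 0.05):
                    assert compute_lsi(A, I, i, eps, 100) == lsi_oracle(A, I, i, eps, 100)

    def test_vectorized_equals_scalar(self, rng):
        A, deg = _ahat_and_degrees(random_connected_adjacency(8, rng))
        I = stationary_influence(A, deg)
        K = compute_all_lsi(A, I, 0.05, 100)
        assert [compute_lsi(A, I, i, 0.05, 100) for i in range(8)] == K.tolist()

    def test_epsilon_monotonicity(self, rng):
        for _ in range(15):
            n = int(rng.integers(3, 10))
            A, deg = _ahat_and_degrees(random_connected_adjacency(n, rng))
            I = stationary_influence(A, deg)
            K_tight = compute_all_lsi(A, I, 0.01, 200)
            K_loose = compute_all_lsi(A, I, 0.1, 200)
            assert np.all(K_tight >= K_loose)

    def test_cap_returns_kmax_with_warning(self, caplog):
        import logging

        A, deg = _ahat_and_degrees(random_connected_adjacency(20, np.random.default_rng(0), p=0.05))
        I = stationary_influence(A, deg)
        with caplog.at_level(logging.WARNING):
            k = compute_lsi(A, I, 0, epsilon=1e-12, k_max=3)
        assert k == 3 and any("k_max" in r.message for r in caplog.records)

    def test_higher_degree_tends_to_smaller_k(self, rng):
        """Well-connected nodes stabilize sooner (statistical tendency)."""
        from scipy.stats import spearmanr

        corrs = []
        for _ in range(15):
            A0 = random_connected_adjacency(20, rng, p=0.15)
            A, deg = _ahat_and_degrees(A0)
            I = stationary_influence(A, deg)
            K = compute_all_lsi(A, I, 0.05, 200)
            if len(set(K.tolist())) > 1:
                corrs.append(spearmanr(deg, K).statistic)
        assert np.mean(corrs) <= 0


class TestSmoothing:
    def test_k0_rows_unchanged_k1_average(self, rng):
        A, _ = _ahat_and_degrees(random_connected_adjacency(5, rng))
        X = rng.normal(size=(5, 3))
        out = ndls_smooth(X, A, np.array([0, 1, 0, 2, 0]))
        assert np.allclose(out[0], X[0]) and np.allclose(out[2], X[2])
        assert np.allclose(out[1], 0.5 * (X[1] + (A @ X)[1]))

    def test_row_stochastic_operator_preserves_constants(self, rng):
        A0 = random_connected_adjacency(6, rng)
        A = normalize_adjacency(A0, self_loops=True, r=1.0)  # row sums 1
        X = np.ones((6, 4)) * 3.7
        out = ndls_smooth(X, A, np.array([0, 1, 2, 3, 4, 5]))
        assert np.allclose(out, 3.7)

    def test_fixed_depth_is_plain_power(self, rng):
        A, _ = _ahat_and_degrees(random_connected_adjacency(6, rng))
        X = rng.normal(size=(6, 2))
        assert np.allclose(fixed_depth_smooth(X, A, 3),
                           np.linalg.matrix_power(A, 3) @ X, atol=1e-12)

    def test_negative_k_rejected(self):
        A, _ = _two_node()
        with pytest.raises(ValueError):
            ndls_smooth(np.ones((2, 1)), A, np.array([-1, 0]))


class TestProfile:
    def test_profile_on_small_hetgraph(self):
        d = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)), index=["d1", "d2", "d3"])
        t = pd.DataFrame(np.random.default_rng(1).normal(size=(2, 4)), index=["t1", "t2"])
        g = assemble_hetgraph(d, t, dd_edges=[("d1", "d2", 0.9)],
                              tt_edges=[("t1", "t2", 0.8)],
                              dt_edges=[("d1", "t1"), ("d3", "t2")])
        prof = ndls_profile(g, NdlsConfig(epsilon=0.1, k_max=40))
        assert prof.smoothed.shape == (5, 4)
        assert np.all(prof.lsi >= 0) and np.all(prof.lsi <= 40)
        frame = prof.to_frame()
        assert list(frame.columns) == ["node_id", "node_type", "K", "degree"]

    def test_fixed_depth_profile_sets_constant_k(self):
        d = pd.DataFrame(np.ones((2, 2)), index=["d1", "d2"])
        t = pd.DataFrame(np.ones((1, 2)), index=["t1"])
        g = assemble_hetgraph(d, t, dt_edges=[("d1", "t1")])
        prof = ndls_profile(g, fixed_depth=4)
        assert set(prof.lsi.tolist()) == {4}
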