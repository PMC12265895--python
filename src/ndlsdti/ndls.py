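"""Node-dependent local smoothing (NDLS) over the heterogeneous graph.

Feature propagation here is parameter-free linear smoothing with the
normalized operator A_hat: after k steps the features are X^(k) =
A_hat^k X, and the influence of node j on node i is exactly (A_hat^k)_ij.
As k grows each row of A_hat^k approaches a stationary influence
distribution that depends only on node degrees within the connected
component — the over-smoothing limit in which nodes become
indistinguishable. For the operator D~^{-r} (A+I) D~^{-(1-r)} the limit
has the closed form (self-looped degrees d~, component volume 2m~):

    I~_ij = d~_i^(1-r) * d~_j^r / (2 m~)   within a component, 0 across.

The local smoothing iteration count of node i at tolerance epsilon is

    K(i, eps) = min { k : || I~_i - row_i(A_hat^k) ||_2 < eps }

and the smoothed embedding averages the propagated features over depths
0..K(i, eps). High-degree, centrally placed nodes reach their limit
sooner (small K); peripheral nodes keep aggregating longer — this
per-node depth is what counters over-smoothing at a fixed global depth.

Self-loops are always added before normalization, which also breaks
bipartiteness so the power iteration converges on every component.
Powers are applied as repeated sparse matrix products; the dense
matrix-power oracle used to validate them lives in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .gcn_encoder import normalize_adjacency
from .hetgraph import HeteroGraph

logger = logging.getLogger(__name__)


@dataclass
class NdlsConfig:
    """Tolerance and propagation settings for the smoothing stage."""

    epsilon: float = 0.05
    k_max: int = 50
    r: float = 0.5
    binarize_edges: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


@dataclass
class NdlsProfile:
    """Per-node smoothing diagnostics plus the smoothed embeddings."""

    node_ids: list[str]
    node_types: np.ndarray
    lsi: np.ndarray          # K(i, eps) per node
    degrees: np.ndarray      # self-looped degrees d~
    smoothed: np.ndarray     # averaged multi-hop embeddings, input width

    def to_frame(self) -> pd.DataFrame:
        """Diagnostics table (node_id, node_type, K, degree)."""
        return pd.DataFrame({
            "node_id": self.node_ids,
            "node_type": self.node_types,
            "K": self.lsi,
            "degree": self.degrees,
        })

    def embeddings(self) -> pd.DataFrame:
        return pd.DataFrame(self.smoothed, index=self.node_ids)


def _union_with_loops(graph: HeteroGraph, config: NdlsConfig):
    A = graph.union_adjacency(binarize=config.binarize_edges)
    A = (A + sparse.identity(graph.n_nodes, format="csr")).tocsr()
    degrees = np.asarray(A.sum(axis=1)).ravel()
    return A, degrees


def propagation_matrix(graph: HeteroGraph, config: NdlsConfig | None = None) -> sparse.csr_matrix:
    """Normalized propagation operator over the union of all edge types.

    Self-loops are always added, so isolated nodes get A_hat = [1].
    """
    config = config or NdlsConfig()
    A, _ = _union_with_loops(graph, config)
    # self-loops are already in A
    return normalize_adjacency(A, self_loops=False, r=config.r)


def influence_row(A_hat, i: int, k: int, k_max: int | None = None) -> np.ndarray:
    """Row i of A_hat^k — the influence of every node on node i after k steps.

    k = 0 returns the indicator row e_i.
    """
    n = A_hat.shape[0]
    if k < 0 or (k_max is not None and k > k_max):
        raise ValueError(f"propagation depth k={k} out of range [0, {k_max}]")
    v = np.zeros(n)
    v[i] = 1.0
    for _ in range(k):
        v = A_hat.T @ v  # e_i^T A_hat^k == ((A_hat^T)^k e_i)^T
    return np.asarray(v).ravel()


def stationary_influence(A_hat, degrees: np.ndarray, r: float = 0.5) -> np.ndarray:
    """Closed-form over-smoothing limit I~ of the rows of A_hat^k.

    ``degrees`` are the self-looped degrees d~ that built ``A_hat``.
    Within each connected component I~_ij = d~_i^(1-r) d~_j^r / (2 m~);
    entries across components are exactly zero.
    """
    n = A_hat.shape[0]
    n_comp, labels = connected_components(A_hat, directed=False)
    I = np.zeros((n, n))
    for c in range(n_comp):
        nodes = np.flatnonzero(labels == c)
        d = degrees[nodes]
        vol = d.sum()
        I[np.ix_(nodes, nodes)] = np.outer(d ** (1.0 - r), d ** r) / vol
    return I


def compute_lsi(A_hat, I_tilde: np.ndarray, i: int,
                epsilon: float = 0.05, k_max: int = 50) -> int:
    """Local smoothing iterations K(i, eps) for one node.

    Smallest k with ||I~_i - row_i(A_hat^k)||_2 < eps; if no k <= k_max
    qualifies, returns k_max with a logged warning.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    target = I_tilde[i]
    n = A_hat.shape[0]
    v = np.zeros(n)
    v[i] = 1.0
    for k in range(k_max + 1):
        if np.linalg.norm(target - v) < epsilon:
            return k
        v = A_hat.T @ v
    logger.warning("node %d: influence row not within eps=%g of its limit by k_max=%d",
                   i, epsilon, k_max)
    return k_max


def compute_all_lsi(A_hat, I_tilde: np.ndarray,
                    epsilon: float = 0.05, k_max: int = 50) -> np.ndarray:
    """Vectorized K(i, eps) for every node (same contract as compute_lsi)."""
    n = A_hat.shape[0]
    M = np.eye(n)  # M = A_hat^k, row i inspected per node
    K = np.full(n, -1, dtype=np.int64)
    for k in range(k_max + 1):
        open_ = K < 0
        if not open_.any():
            break
        dist = np.linalg.norm(I_tilde[open_] - M[open_], axis=1)
        hit = np.flatnonzero(open_)[dist < epsilon]
        K[hit] = k
        if k < k_max:
            M = (A_hat.T @ M.T).T
    unresolved = K < 0
    if unresolved.any():
        logger.warning("%d nodes not within eps=%g of their limit by k_max=%d",
                       int(unresolved.sum()), epsilon, k_max)
        K[unresolved] = k_max
    return K


def ndls_smooth(X: np.ndarray, A_hat, K: np.ndarray) -> np.ndarray:
    """Average each node's propagated features over depths 0..K_i.

    Row i of the result is mean(X^(0)_i, ..., X^(K_i)_i) with
    X^(k) = A_hat^k X; a node with K_i = 0 keeps its input row.
    """
    X = np.asarray(X, dtype=float)
    K = np.asarray(K)
    if np.any(K < 0):
        raise ValueError("per-node depths K must be non-negative")
    acc = X.copy()
    running = X
    for k in range(1, int(K.max()) + 1 if len(K) else 1):
        running = A_hat @ running
        rows = K >= k
        acc[rows] += running[rows]
    return acc / (K + 1)[:, None]


def fixed_depth_smooth(X: np.ndarray, A_hat, k: int) -> np.ndarray:
    """Plain fixed-depth propagation A_hat^k X (the non-adaptive baseline)."""
    if k < 0:
        raise ValueError("depth must be non-negative")
    out = np.asarray(X, dtype=float)
    for _ in range(k):
        out = A_hat @ out
    return out


def ndls_profile(graph: HeteroGraph, config: NdlsConfig | None = None,
                 fixed_depth: int | None = None) -> NdlsProfile:
    """Run the full smoothing stage on a heterogeneous graph.

    With ``fixed_depth`` set, adaptive depths are bypassed and every node
    is propagated exactly that many steps (the fixed-depth GCN baseline
    used in the depth-sweep comparison); K then records the fixed depth.
    """
    config = config or NdlsConfig()
    A_hat = propagation_matrix(graph, config)
    _, degrees = _union_with_loops(graph, config)
    if fixed_depth is not None:
        K = np.full(graph.n_nodes, int(fixed_depth), dtype=np.int64)
        smoothed = fixed_depth_smooth(graph.node_features, A_hat, int(fixed_depth))
    else:
        I_tilde = stationary_influence(A_hat, degrees, config.r)
        K = compute_all_lsi(A_hat, I_tilde, config.epsilon, config.k_max)
        smoothed = ndls_smooth(graph.node_features, A_hat, K)
    return NdlsProfile(node_ids=list(graph.node_ids), node_types=graph.node_types.copy(),
                       lsi=K, degrees=degrees, smoothed=smoothed)
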