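"""Independent oracles and small-graph utilities shared by the tests.

Everything here deliberately avoids the package's own computation paths:
local alignment is re-derived by memoized recursion over start positions,
influence rows come from explicit dense matrix powers, and AUC is the
Mann-Whitney rank statistic.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import rankdata


def sw_oracle(a: str, b: str, match: float = 3, mismatch: float = -3,
              gap: float = -2) -> float:
    """Best local-alignment score by recursion over all start/stop choices.

    For every start pair (i, j) the recursion explores extending by a
    substitution or a (linear) gap or stopping, i.e. it scores every
    local alignment of every substring pair; memoization only collapses
    repeated subproblems.
    """

    @lru_cache(maxsize=None)
    def best_from(i: int, j: int) -> float:
        options = [0.0]  # stop: the empty extension
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best_from(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best_from(i + 1, j))
        if j < len(b):
            options.append(gap + best_from(i, j + 1))
        return max(options)

    return max(best_from(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1))


def influence_oracle(A_hat, i: int, k: int) -> np.ndarray:
    """Row i of A_hat^k via explicit dense matrix power."""
    M = np.linalg.matrix_power(np.asarray(A_hat.todense() if hasattr(A_hat, "todense")
                                          else A_hat, dtype=float), k)
    return M[i]


def lsi_oracle(A_hat, I_tilde: np.ndarray, i: int, epsilon: float, k_max: int) -> int:
    """Brute-force linear search over k using dense matrix-power rows."""
    for k in range(k_max + 1):
        if np.linalg.norm(I_tilde[i] - influence_oracle(A_hat, i, k)) < epsilon:
            return k
    return k_max


def rank_auc(labels, scores) -> float:
    """AUC as the Mann-Whitney U statistic (midranks handle ties)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def random_connected_adjacency(n: int, rng: np.random.Generator,
                               p: float = 0.3) -> np.ndarray:
    """Symmetric binary adjacency of a connected Erdos-Renyi-plus-path graph."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    for i in range(n - 1):  # spanning path guarantees connectivity
        A[i, i + 1] = 1
    return A + A.T
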