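"""Graph-convolution encoder for molecular and sequence graphs.

Both entity types share the same architecture: ``num_layers`` rounds of
normalized neighbourhood aggregation

    X^(k) = sigma( A_hat X^(k-1) W^(k-1) ),    A_hat = D~^{-r} (A + I) D~^{-(1-r)}

followed by mean pooling over nodes, yielding one ``output_dim``-wide
vector (default 128) per drug and per target. The nonlinearity is applied
between layers; the final layer is linear so the pooled embedding keeps
both signs. Drug graphs feed their raw 5-element integer atom features to
the first layer; sequence graphs first expand their scalar residue codes
through a learned embedding lookup.

Because the graphs are small (tens of atoms, at most a few thousand
residues), the encoder is plain NumPy with hand-written backpropagation
and an Adam optimizer — every forward and backward pass is a handful of
small dense/sparse matrix products, and all randomness flows from one
seed, which makes training bitwise reproducible.

Training (``train_encoders``) is joint supervised link prediction: both
encoders plus a temporary bilinear head are fitted with full-batch Adam
on binary cross-entropy over labelled drug-target pairs; the head is
discarded and the frozen encoders supply the initial node features of the
heterogeneous graph.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.metrics import roc_auc_score

from .chem_graph import MolecularGraph
from .prot_graph import SequenceGraph

_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda pre: (pre > 0).astype(float)),
    "identity": (lambda x: x, lambda pre: np.ones_like(pre)),
}


@dataclass
class EncoderConfig:
    """Architecture and training settings shared by both encoders.

    ``r`` is the normalization exponent of the propagation operator
    (0.5 = symmetric normalization); ``residue_embed_dim`` is the width of
    the learned residue-code embedding (default 5, matching the drug atom
    feature width).
    """

    num_layers: int = 2
    hidden_dim: int = 64
    output_dim: int = 128
    activation: str = "relu"
    self_loops: bool = True
    r: float = 0.5
    seed: int = 0
    residue_vocab: int = 21  # codes 0..20: unknown + 20 standard residues
    residue_embed_dim: int = 5
    # training (joint link-prediction objective)
    epochs: int = 60
    learning_rate: float = 0.02
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.num_layers < 1 or self.output_dim < 1 or self.hidden_dim < 1:
            raise ValueError("num_layers, hidden_dim and output_dim must be positive")
        if not 0.0 < self.r <= 1.0:
            raise ValueError("norm exponent r must lie in (0, 1]")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def normalize_adjacency(A, self_loops: bool = True, r: float = 0.5):
    """Normalized propagation operator D~^{-r} (A [+ I]) D~^{-(1-r)}.

    Accepts a dense symmetric array or a scipy sparse matrix and returns
    the same kind. With ``r=0.5`` this is the symmetric normalization;
    with ``r=1`` every row sums to one (random-walk operator). A zero-degree
    node without self-loops raises ``ValueError``.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("norm exponent r must lie in (0, 1]")
    is_sparse = sparse.issparse(A)
    n = A.shape[0]
    if is_sparse:
        At = A.astype(float)
        if self_loops:
            At = At + sparse.identity(n, format="csr")
        deg = np.asarray(At.sum(axis=1)).ravel()
        if np.any(deg == 0):
            raise ValueError("zero-degree node; enable self_loops or connect the node")
        left = sparse.diags(deg ** (-r))
        right = sparse.diags(deg ** (-(1.0 - r)))
        return (left @ At @ right).tocsr()
    At = np.asarray(A, dtype=float)
    if self_loops:
        At = At + np.eye(n)
    deg = At.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("zero-degree node; enable self_loops or connect the node")
    return (deg ** (-r))[:, None] * At * (deg ** (-(1.0 - r)))[None, :]


def gcn_layer(X: np.ndarray, A_hat, W: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One graph-convolution step sigma(A_hat X W)."""
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"dimension mismatch: X has {X.shape[1]} features, W expects {W.shape[0]}")
    act, _ = _ACTIVATIONS[activation]
    return act((A_hat @ X) @ W)


def mean_readout(node_embeddings: np.ndarray) -> np.ndarray:
    """Coordinatewise mean over nodes (permutation-invariant readout)."""
    node_embeddings = np.asarray(node_embeddings, dtype=float)
    if node_embeddings.ndim != 2 or node_embeddings.shape[0] == 0:
        raise ValueError("readout requires a non-empty (n_nodes, width) matrix")
    return node_embeddings.mean(axis=0)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class GCNEncoder:
    """A stack of graph-convolution layers with mean readout.

    ``embed_table`` is ``None`` for drug graphs (raw atom features) and a
    ``(residue_vocab, residue_embed_dim)`` array for sequence graphs.
    """

    def __init__(self, config: EncoderConfig, weights: list[np.ndarray],
                 embed_table: np.ndarray | None = None):
        self.config = config
        self.weights = weights
        self.embed_table = embed_table
        self._ahat_cache: dict[str, object] = {}

    # -- construction -------------------------------------------------
    @classmethod
    def random(cls, config: EncoderConfig, input_dim: int,
               embed_vocab: int | None = None, seed: int | None = None) -> "GCNEncoder":
        """Glorot-initialized encoder with frozen random weights."""
        rng = np.random.default_rng(config.seed if seed is None else seed)
        table = None
        if embed_vocab is not None:
            table = rng.normal(scale=0.5, size=(embed_vocab, input_dim))
        dims = [input_dim] + [config.hidden_dim] * (config.num_layers - 1) + [config.output_dim]
        weights = [_glorot(rng, dims[i], dims[i + 1]) for i in range(config.num_layers)]
        return cls(config, weights, table)

    # -- forward ------------------------------------------------------
    def _graph_key(self, graph) -> str:
        return getattr(graph, "drug_id", None) or getattr(graph, "target_id", None) or str(id(graph))

    def _a_hat(self, graph):
        key = self._graph_key(graph)
        ahat = self._ahat_cache.get(key)
        if ahat is None:
            ahat = normalize_adjacency(graph.adjacency, self.config.self_loops, self.config.r)
            if sparse.issparse(ahat) and ahat.shape[0] <= 512:
                ahat = ahat.toarray()  # dense matmul beats sparse overhead on small graphs
            self._ahat_cache[key] = ahat
        return ahat

    def input_features(self, graph) -> np.ndarray:
        if isinstance(graph, SequenceGraph) or (
            self.embed_table is not None and hasattr(graph, "residue_codes")
        ):
            if self.embed_table is None:
                raise ValueError("sequence graph given to an encoder without an embedding table")
            return self.embed_table[graph.residue_codes]
        return np.asarray(graph.atom_features, dtype=float)

    def forward(self, graph, with_cache: bool = False):
        """Node-level forward pass; optionally return backprop caches."""
        cfg = self.config
        act, _ = _ACTIVATIONS[cfg.activation]
        A_hat = self._a_hat(graph)
        X = self.input_features(graph)
        caches = []
        for layer, W in enumerate(self.weights):
            P = A_hat @ X
            pre = P @ W
            X = act(pre) if layer < len(self.weights) - 1 else pre
            if with_cache:
                caches.append((P, pre))
        if with_cache:
            return X, (A_hat, caches)
        return X

    def embed(self, graph) -> np.ndarray:
        """Graph-level embedding: mean readout over the node embeddings."""
        return mean_readout(self.forward(graph))

    # -- backward (used by train_encoders) ----------------------------
    def backward(self, graph, dz: np.ndarray, cache) -> tuple[list[np.ndarray], np.ndarray | None]:
        """Gradients of a scalar loss wrt weights (and embed table rows).

        ``dz`` is the gradient at the pooled graph embedding; ``cache`` is
        the second return of ``forward(..., with_cache=True)``.
        """
        A_hat, caches = cache
        _, dact = _ACTIVATIONS[self.config.activation]
        n = caches[0][0].shape[0]
        L = len(self.weights)
        dX = np.tile(dz / n, (n, 1))  # gradient of mean readout
        dWs: list[np.ndarray] = [None] * L  # type: ignore[list-item]
        for layer in reversed(range(L)):
            P, pre = caches[layer]
            dpre = dX if layer == L - 1 else dX * dact(pre)
            dWs[layer] = P.T @ dpre
            dP = dpre @ self.weights[layer].T
            dX = A_hat.T @ dP
        dtable = None
        if self.embed_table is not None:
            dtable = np.zeros_like(self.embed_table)
            np.add.at(dtable, graph.residue_codes, dX)
        return dWs, dtable


def encode_entity(graph: MolecularGraph | SequenceGraph, encoder: GCNEncoder) -> np.ndarray:
    """Embed one entity graph with a (fixed-weight) encoder."""
    return encoder.embed(graph)


def embed_all(encoder: GCNEncoder, graphs: Mapping[str, object]) -> "pd.DataFrame":
    """Embed every graph; rows indexed by entity id."""
    import pandas as pd

    ids = list(graphs)
    mat = np.vstack([encoder.embed(graphs[i]) for i in ids]) if ids else np.zeros((0, encoder.config.output_dim))
    return pd.DataFrame(mat, index=ids)


# ---------------------------------------------------------------------
# joint training
# ---------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedEncoders:
    """Frozen encoders plus the training trace (loss per epoch, val AUC)."""

    drug_encoder: GCNEncoder
    target_encoder: GCNEncoder
    history: list[dict] = field(default_factory=list)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_encoders(
    train_pairs: Iterable[tuple[str, str, int]],
    drug_graphs: Mapping[str, MolecularGraph],
    target_graphs: Mapping[str, SequenceGraph],
    config: EncoderConfig | None = None,
) -> TrainedEncoders:
    """Jointly fit both encoders by supervised link prediction.

    A bilinear head sigma(z_d^T W_h z_t + b) scores each labelled pair;
    encoders and head are optimized together with full-batch Adam on
    binary cross-entropy. A stratified validation slice
    (``config.val_fraction``) tracks AUC, and the parameters from the best
    validation epoch are kept; the head is then discarded. Deterministic
    given ``config.seed``.
    """
    config = config or EncoderConfig()
    pairs = list(train_pairs)
    labels = np.array([int(p[2]) for p in pairs])
    if len(np.unique(labels)) < 2:
        raise ValueError("training pairs must contain both classes")

    rng = np.random.default_rng(config.seed)

    drug_ids = sorted({p[0] for p in pairs})
    target_ids = sorted({p[1] for p in pairs})
    d_index = {d: i for i, d in enumerate(drug_ids)}
    t_index = {t: i for i, t in enumerate(target_ids)}
    pd_idx = np.array([d_index[p[0]] for p in pairs])
    pt_idx = np.array([t_index[p[1]] for p in pairs])

    # stratified validation split
    val_mask = np.zeros(len(pairs), dtype=bool)
    if config.val_fraction > 0:
        for cls in (0, 1):
            idx = np.flatnonzero(labels == cls)
            n_val = int(round(config.val_fraction * len(idx)))
            if n_val >= 1 and n_val < len(idx):
                val_mask[rng.choice(idx, size=n_val, replace=False)] = True
    if val_mask.any() and len(np.unique(labels[val_mask])) < 2:
        val_mask[:] = False
    tr = ~val_mask

    d_enc = GCNEncoder.random(config, input_dim=5, seed=int(rng.integers(2**31 - 1)))
    t_enc = GCNEncoder.random(
        config, input_dim=config.residue_embed_dim, embed_vocab=config.residue_vocab,
        seed=int(rng.integers(2**31 - 1)),
    )
    d = config.output_dim
    Wh = rng.normal(scale=1.0 / np.sqrt(d), size=(d, d))
    bias = np.zeros(1)

    params = d_enc.weights + t_enc.weights + [t_enc.embed_table, Wh, bias]
    opt = _Adam(params, config.learning_rate)

    dg = [drug_graphs[i] for i in drug_ids]
    tg = [target_graphs[i] for i in target_ids]

    def all_scores() -> np.ndarray:
        Zd = np.vstack([d_enc.embed(g) for g in dg])
        Zt = np.vstack([t_enc.embed(g) for g in tg])
        return _sigmoid(np.einsum("ij,jk,ik->i", Zd[pd_idx], Wh, Zt[pt_idx]) + bias[0])

    history: list[dict] = []
    best = (-np.inf, None)
    n_tr = int(tr.sum())
    for epoch in range(config.epochs):
        fwd_d = [d_enc.forward(g, with_cache=True) for g in dg]
        fwd_t = [t_enc.forward(g, with_cache=True) for g in tg]
        Zd = np.vstack([mean_readout(x) for x, _ in fwd_d])
        Zt = np.vstack([mean_readout(x) for x, _ in fwd_t])

        zd, zt = Zd[pd_idx[tr]], Zt[pt_idx[tr]]
        logits = np.einsum("ij,jk,ik->i", zd, Wh, zt) + bias[0]
        p = _sigmoid(logits)
        y = labels[tr].astype(float)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))

        sgrad = (p - y) / n_tr
        dWh = zd.T @ (sgrad[:, None] * zt)
        dbias = np.array([sgrad.sum()])
        dZd = np.zeros_like(Zd)
        dZt = np.zeros_like(Zt)
        np.add.at(dZd, pd_idx[tr], sgrad[:, None] * (zt @ Wh.T))
        np.add.at(dZt, pt_idx[tr], sgrad[:, None] * (zd @ Wh))

        grads_d = [np.zeros_like(W) for W in d_enc.weights]
        for i, (x, cache) in enumerate(fwd_d):
            if not dZd[i].any():
                continue
            dWs, _ = d_enc.backward(dg[i], dZd[i], cache)
            for acc, g in zip(grads_d, dWs):
                acc += g
        grads_t = [np.zeros_like(W) for W in t_enc.weights]
        dtable = np.zeros_like(t_enc.embed_table)
        for i, (x, cache) in enumerate(fwd_t):
            if not dZt[i].any():
                continue
            dWs, dt = t_enc.backward(tg[i], dZt[i], cache)
            for acc, g in zip(grads_t, dWs):
                acc += g
            dtable += dt

        opt.step(params, grads_d + grads_t + [dtable, dWh, dbias])

        rec = {"epoch": epoch, "loss": float(loss)}
        # validation AUC every few epochs (re-embeds everything, so not each step)
        if val_mask.any() and (epoch % 5 == 4 or epoch == config.epochs - 1):
            val_scores = all_scores()[val_mask]
            rec["val_auc"] = float(roc_auc_score(labels[val_mask], val_scores))
            if rec["val_auc"] > best[0]:
                best = (rec["val_auc"], [p.copy() for p in params])
        history.append(rec)

    if best[1] is not None:
        for p, bp in zip(params, best[1]):
            p[...] = bp

    d_enc._ahat_cache.clear()
    t_enc._ahat_cache.clear()
    return TrainedEncoders(drug_encoder=d_enc, target_encoder=t_enc, history=history)
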