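"""Heterogeneous drug-target graph construction.

Three edge types connect the two node types:

* ``dd`` — drug-drug edges from Tanimoto similarity of Morgan (circular)
  fingerprints, default radius 2 over 2048 bits;
* ``tt`` — target-target edges from Smith-Waterman local alignment
  scores, normalized by the geometric mean of the self-alignment scores
  so that values live in [0, 1];
* ``dt`` — known drug-target interactions (weight 1).

Similarity edges are sparsified by a threshold plus an optional mutual
top-k cap per node (ties broken by entity id), since an unthresholded
similarity graph is complete. Smith-Waterman alignment is delegated to
Biopython's PairwiseAligner in local mode; an exhaustive small-instance
oracle in the test-suite cross-checks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_graph import MolecularGraph, SmilesParseError

NODE_DRUG = "drug"
NODE_TARGET = "target"
EDGE_TYPES = ("dd", "tt", "dt")


@dataclass
class SimilarityConfig:
    """Fingerprint, alignment-scoring and sparsification settings."""

    fp_radius: int = 2
    fp_bits: int = 2048
    dd_threshold: float = 0.5
    tt_threshold: float = 0.5
    topk: int | None = 5
    matrix: str | None = "BLOSUM62"   # None -> simple match/mismatch scoring
    match: float = 3.0
    mismatch: float = -3.0
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dd_threshold", "tt_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.topk is not None and self.topk < 1:
            raise ValueError("topk must be >= 1 when set")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties are given as positive magnitudes")


# ---------------------------------------------------------------------
# drug side: fingerprints + Tanimoto
# ---------------------------------------------------------------------

def tanimoto(fp_a: frozenset | set, fp_b: frozenset | set) -> float:
    """Tanimoto coefficient |a & b| / |a | b| on sets of on-bit indices."""
    a, b = set(fp_a), set(fp_b)
    union = len(a | b)
    if union == 0:
        raise ValueError("Tanimoto undefined for two empty bitsets")
    return len(a & b) / union


def drug_fingerprint(mol: MolecularGraph | str, config: SimilarityConfig | None = None) -> frozenset:
    """Morgan circular fingerprint as the set of on-bit indices."""
    config = config or SimilarityConfig()
    smiles = mol.smiles if isinstance(mol, MolecularGraph) else mol
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise SmilesParseError(f"cannot fingerprint unparsable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=config.fp_radius, fpSize=config.fp_bits)
    return frozenset(gen.GetFingerprint(rd).GetOnBits())


def drug_similarity_matrix(
    graphs: Mapping[str, MolecularGraph] | Mapping[str, str],
    config: SimilarityConfig | None = None,
) -> pd.DataFrame:
    """Pairwise Tanimoto similarity; rows/columns indexed by drug id."""
    config = config or SimilarityConfig()
    ids = list(graphs)
    fps = [drug_fingerprint(graphs[i], config) for i in ids]
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = tanimoto(fps[i], fps[j])
    return pd.DataFrame(S, index=ids, columns=ids)


# ---------------------------------------------------------------------
# target side: Smith-Waterman
# ---------------------------------------------------------------------

@lru_cache(maxsize=16)
def _aligner(matrix: str | None, match: float, mismatch: float,
             gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def smith_waterman(seq_a: str, seq_b: str, config: SimilarityConfig | None = None) -> float:
    """Maximal local-alignment score (dynamic programming, floored at 0)."""
    config = config or SimilarityConfig()
    if not seq_a or not seq_b:
        raise ValueError("Smith-Waterman requires non-empty sequences")
    aligner = _aligner(config.matrix, config.match, config.mismatch,
                       config.gap_open, config.gap_extend)
    return float(aligner.score(seq_a, seq_b))


def normalized_sw(seq_a: str, seq_b: str, config: SimilarityConfig | None = None,
                  self_a: float | None = None, self_b: float | None = None) -> float:
    """SW(a,b) / sqrt(SW(a,a) * SW(b,b)); 1 for identical sequences.

    Self-alignment scores may be passed in to avoid recomputation.
    """
    config = config or SimilarityConfig()
    saa = smith_waterman(seq_a, seq_a, config) if self_a is None else self_a
    sbb = smith_waterman(seq_b, seq_b, config) if self_b is None else self_b
    if saa <= 0 or sbb <= 0:
        raise ValueError("normalized SW undefined: zero self-alignment score")
    return smith_waterman(seq_a, seq_b, config) / float(np.sqrt(saa * sbb))


def target_similarity_matrix(
    sequences: Mapping[str, str],
    config: SimilarityConfig | None = None,
) -> pd.DataFrame:
    """Pairwise normalized Smith-Waterman similarity, indexed by target id."""
    config = config or SimilarityConfig()
    ids = list(sequences)
    seqs = [sequences[i] for i in ids]
    selfs = [smith_waterman(s, s, config) for s in seqs]
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = normalized_sw(seqs[i], seqs[j], config, selfs[i], selfs[j])
    return pd.DataFrame(S, index=ids, columns=ids)


# ---------------------------------------------------------------------
# edge construction + assembly
# ---------------------------------------------------------------------

def build_similarity_edges(
    similarity: pd.DataFrame,
    threshold: float,
    topk: int | None = None,
) -> list[tuple[str, str, float]]:
    """Edges (id_a, id_b, weight) for pairs with similarity >= threshold.

    With ``topk`` set, a pair additionally survives only if each endpoint
    ranks the other among its ``topk`` most-similar neighbours (mutual
    top-k, which strictly caps every node's degree); ties are broken by
    lexicographic entity id.
    """
    ids = list(similarity.index)
    S = similarity.to_numpy()
    n = len(ids)
    keep = {}
    if topk is not None:
        for i in range(n):
            order = sorted((j for j in range(n) if j != i), key=lambda j: (-S[i, j], ids[j]))
            keep[i] = set(order[:topk])
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if S[i, j] < threshold:
                continue
            if topk is not None and (j not in keep[i] or i not in keep[j]):
                continue
            edges.append((ids[i], ids[j], float(S[i, j])))
    return edges


@dataclass
class HeteroGraph:
    """Typed drug/target graph with a shared feature matrix.

    ``node_ids`` orders all nodes (drugs first, then targets);
    ``edges[etype]`` holds deduplicated (i, j, weight) index triples with
    i < j for dd/tt and (drug index, target index) for dt;
    ``node_features`` rows align with ``node_ids``.
    """

    node_ids: list[str]
    node_types: np.ndarray
    edges: dict[str, list[tuple[int, int, float]]]
    node_features: np.ndarray
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {nid: k for k, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def n_edges(self, etype: str | None = None) -> int:
        if etype is not None:
            return len(self.edges.get(etype, []))
        return sum(len(v) for v in self.edges.values())

    def dt_pairs(self) -> set[tuple[str, str]]:
        """Drug-target id pairs currently wired as dt edges."""
        return {(self.node_ids[i], self.node_ids[j]) for i, j, _ in self.edges.get("dt", [])}

    def union_adjacency(self, binarize: bool = True):
        """Symmetric adjacency over all edge types (scipy CSR, no self-loops)."""
        from scipy import sparse

        rows, cols, vals = [], [], []
        for triples in self.edges.values():
            for i, j, w in triples:
                v = 1.0 if binarize else w
                rows += [i, j]
                cols += [j, i]
                vals += [v, v]
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(self.n_nodes, self.n_nodes))
        if binarize:
            A.data[:] = np.minimum(A.data, 1.0)
        return A


def assemble_hetgraph(
    drug_embeddings: pd.DataFrame,
    target_embeddings: pd.DataFrame,
    dd_edges: Iterable[tuple[str, str, float]] = (),
    tt_edges: Iterable[tuple[str, str, float]] = (),
    dt_edges: Iterable[tuple[str, str]] = (),
) -> HeteroGraph:
    """Assemble the typed graph from embeddings and id-level edge lists.

    dt edges carry weight 1. Self-edges are rejected, duplicates (in
    either orientation) collapse to one edge, and an edge endpoint absent
    from the embeddings raises ``KeyError`` naming the id.
    """
    if drug_embeddings.shape[1] != target_embeddings.shape[1]:
        raise ValueError("drug and target embeddings must share their width")
    node_ids = list(drug_embeddings.index) + list(target_embeddings.index)
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("drug and target ids must be disjoint and unique")
    types = np.array([NODE_DRUG] * len(drug_embeddings) + [NODE_TARGET] * len(target_embeddings))
    index = {nid: k for k, nid in enumerate(node_ids)}
    feats = np.vstack([drug_embeddings.to_numpy(float), target_embeddings.to_numpy(float)]) \
        if node_ids else np.zeros((0, drug_embeddings.shape[1]))

    def resolve(eid: str, want: str) -> int:
        if eid not in index:
            raise KeyError(f"edge endpoint {eid!r} is not a known {want}")
        k = index[eid]
        if types[k] != want:
            raise ValueError(f"edge endpoint {eid!r} is a {types[k]}, expected a {want}")
        return k

    edges: dict[str, list[tuple[int, int, float]]] = {"dd": [], "tt": [], "dt": []}
    for etype, triples, ta, tb in (
        ("dd", dd_edges, NODE_DRUG, NODE_DRUG),
        ("tt", tt_edges, NODE_TARGET, NODE_TARGET),
    ):
        seen = set()
        for a, b, w in triples:
            i, j = resolve(a, ta), resolve(b, tb)
            if i == j:
                raise ValueError(f"self-edge on {a!r}")
            if not 0.0 < w <= 1.0:
                raise ValueError(f"{etype} edge ({a!r}, {b!r}) weight {w} outside (0, 1]")
            i, j = min(i, j), max(i, j)
            if (i, j) in seen:
                continue
            seen.add((i, j))
            edges[etype].append((i, j, float(w)))
    seen_dt = set()
    for a, b in dt_edges:
        i, j = resolve(a, NODE_DRUG), resolve(b, NODE_TARGET)
        if (i, j) in seen_dt:
            continue
        seen_dt.add((i, j))
        edges["dt"].append((i, j, 1.0))
    return HeteroGraph(node_ids=node_ids, node_types=types, edges=edges,
                       node_features=feats, index=index)
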