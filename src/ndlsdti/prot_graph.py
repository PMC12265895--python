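"""Protein sequences as integer-coded chain graphs.

A target sequence becomes a path graph: one node per residue, edges
between consecutive positions only (backbone order; no contact map or
structural input is consumed). Each node carries a single integer code
from an amino-acid index dictionary; code 0 is reserved for residues
outside the dictionary. The graph-convolution encoder expands these
scalar codes through a learned embedding lookup before its first layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically by one-letter code.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Code reserved for residues absent from the dictionary.
UNKNOWN_CODE = 0

#: Default residue cap; longer sequences are truncated with a warning.
DEFAULT_MAX_RESIDUES = 1200


@dataclass
class SequenceGraph:
    """Chain graph of one target sequence.

    Attributes
    ----------
    target_id : str
    residue_codes : ndarray of int, shape (n,)
        Dictionary code of each residue (0 = unknown).
    adjacency : scipy.sparse.csr_matrix, shape (n, n)
        Symmetric binary chain adjacency: edges (i, i+1) only.
    sequence : str
        The (possibly truncated) normalized sequence.
    """

    target_id: str
    residue_codes: np.ndarray
    adjacency: sparse.csr_matrix
    sequence: str

    @property
    def n_residues(self) -> int:
        return len(self.residue_codes)

    def validate(self) -> None:
        n = self.n_residues
        if n != len(self.sequence):
            raise ValueError(f"{self.target_id}: codes/sequence length mismatch")
        if self.adjacency.shape != (n, n):
            raise ValueError(f"{self.target_id}: adjacency shape mismatch")
        expected = chain_adjacency(n)
        if (self.adjacency != expected).nnz != 0:
            raise ValueError(f"{self.target_id}: adjacency is not the sequential chain")


def build_index_dictionary(alphabet: str = STANDARD_AMINO_ACIDS) -> dict[str, int]:
    """Map each symbol of ``alphabet`` to 1..len(alphabet), in alphabet order.

    Code 0 stays reserved for unknown residues and is never assigned.
    Duplicate symbols raise ``ValueError``.
    """
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet contains duplicate symbols")
    return {sym: i + 1 for i, sym in enumerate(alphabet)}


def chain_adjacency(n: int) -> sparse.csr_matrix:
    """Symmetric binary adjacency of a path graph on ``n`` nodes."""
    if n < 2:
        return sparse.csr_matrix((n, n), dtype=np.uint8)
    off = np.ones(n - 1, dtype=np.uint8)
    return sparse.diags([off, off], offsets=[-1, 1], format="csr", dtype=np.uint8)


def normalize_sequence(sequence: str) -> str:
    """Uppercase, strip gaps ('-', '.') and terminal '*' markers."""
    return sequence.upper().replace("-", "").replace(".", "").replace("*", "")


def encode_sequence(
    sequence: str,
    dictionary: dict[str, int] | None = None,
    target_id: str = "",
    max_residues: int = DEFAULT_MAX_RESIDUES,
) -> SequenceGraph:
    """Encode one amino-acid sequence as a :class:`SequenceGraph`.

    Residues missing from ``dictionary`` get code 0. Sequences longer than
    ``max_residues`` are truncated with a logged warning (bounded memory).
    An empty sequence (after normalization) raises ``ValueError``.
    """
    if dictionary is None:
        dictionary = build_index_dictionary()
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValueError(f"empty sequence for target {target_id!r}")
    if len(seq) > max_residues:
        logger.warning(
            "target %s: sequence length %d exceeds cap %d; truncating",
            target_id, len(seq), max_residues,
        )
        seq = seq[:max_residues]
    codes = np.array([dictionary.get(ch, UNKNOWN_CODE) for ch in seq], dtype=np.int64)
    return SequenceGraph(
        target_id=target_id,
        residue_codes=codes,
        adjacency=chain_adjacency(len(seq)),
        sequence=seq,
    )


def encode_sequence_table(
    records: "list[tuple[str, str]]",
    dictionary: dict[str, int] | None = None,
    max_residues: int = DEFAULT_MAX_RESIDUES,
) -> dict[str, SequenceGraph]:
    """Encode ``(target_id, sequence)`` records; duplicate ids are rejected."""
    graphs: dict[str, SequenceGraph] = {}
    for target_id, seq in records:
        if target_id in graphs:
            raise ValueError(f"duplicate target id {target_id!r}")
        graphs[target_id] = encode_sequence(seq, dictionary, target_id, max_residues)
    return graphs
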