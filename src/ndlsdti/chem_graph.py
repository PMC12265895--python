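"""Molecular graphs from SMILES.

Each drug is represented as a graph over its heavy atoms: hydrogens stay
implicit and contribute only to the per-atom hydrogen count. Every atom
carries a 5-element integer feature vector

    [z, b, h, q, c]

where ``z`` is the atomic number, ``b`` the number of bonds to heavy
neighbours (the degree in the adjacency matrix), ``h`` the attached
hydrogen count (implicit + explicit), ``q`` the total valence, and ``c``
a 0/1 aromaticity flag. Bond orders are not encoded: the adjacency matrix
is binary, matching the single unweighted propagation operator used by
the graph-convolution encoder downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger

# RDKit reports parse failures on its own logger; we raise instead.
RDLogger.DisableLog("rdApp.error")

ATOM_FEATURE_NAMES = ("atomic_num", "heavy_degree", "n_hydrogens", "valence", "is_aromatic")


class SmilesParseError(ValueError):
    """Raised when a SMILES record cannot be turned into a molecular graph."""


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one drug molecule.

    Attributes
    ----------
    drug_id : str
        Identifier of the record the graph was built from.
    atom_features : ndarray of shape (n_atoms, 5), int
        Per-atom ``[z, b, h, q, c]`` vectors.
    adjacency : ndarray of shape (n_atoms, n_atoms), uint8
        Symmetric binary bond matrix with zero diagonal.
    smiles : str
        The SMILES string the graph was parsed from.
    """

    drug_id: str
    atom_features: np.ndarray
    adjacency: np.ndarray
    smiles: str

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return int(self.adjacency.sum()) // 2

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        feats, adj = self.atom_features, self.adjacency
        if feats.ndim != 2 or feats.shape[1] != 5:
            raise ValueError(f"{self.drug_id}: atom_features must be (n, 5)")
        n = feats.shape[0]
        if adj.shape != (n, n):
            raise ValueError(f"{self.drug_id}: adjacency shape {adj.shape} != ({n}, {n})")
        if not np.array_equal(adj, adj.T):
            raise ValueError(f"{self.drug_id}: adjacency not symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError(f"{self.drug_id}: adjacency has self-edges")
        if np.any(feats[:, 0] < 1):
            raise ValueError(f"{self.drug_id}: atomic number < 1")
        if not np.isin(feats[:, 4], (0, 1)).all():
            raise ValueError(f"{self.drug_id}: aromatic flag not in {{0, 1}}")
        if not np.array_equal(feats[:, 1], adj.sum(axis=1)):
            raise ValueError(f"{self.drug_id}: heavy degree inconsistent with adjacency")


def atom_feature_vector(atom: Chem.Atom) -> list[int]:
    """Return ``[z, b, h, q, c]`` for an RDKit atom (heavy neighbours only in b)."""
    heavy_degree = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
    return [
        atom.GetAtomicNum(),
        heavy_degree,
        atom.GetTotalNumHs(),
        atom.GetTotalValence(),
        int(atom.GetIsAromatic()),
    ]


def parse_smiles(smiles: str, drug_id: str) -> MolecularGraph:
    """Parse one SMILES string into a :class:`MolecularGraph`.

    Raises
    ------
    SmilesParseError
        If the SMILES is syntactically invalid or describes an empty
        molecule; the message names the offending record.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES for drug {drug_id!r}: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"empty molecule for drug {drug_id!r}: {smiles!r}")
    feats = np.array([atom_feature_vector(a) for a in mol.GetAtoms()], dtype=np.int64)
    n = mol.GetNumAtoms()
    adj = np.zeros((n, n), dtype=np.uint8)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1
    graph = MolecularGraph(drug_id=drug_id, atom_features=feats, adjacency=adj, smiles=smiles)
    graph.validate()
    return graph


def parse_smiles_table(records: "list[tuple[str, str]]") -> dict[str, MolecularGraph]:
    """Parse ``(drug_id, smiles)`` records; duplicate ids are rejected."""
    graphs: dict[str, MolecularGraph] = {}
    for drug_id, smiles in records:
        if drug_id in graphs:
            raise ValueError(f"duplicate drug id {drug_id!r}")
        graphs[drug_id] = parse_smiles(smiles, drug_id)
    return graphs
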