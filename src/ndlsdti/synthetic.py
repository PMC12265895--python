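"""Synthetic drug/target worlds with planted interaction structure.

The generator emulates the joint structure the predictor exploits in
real interaction data: entities fall into latent clusters, a drug and a
target interact with high probability ``p_in`` when they share a cluster
and low probability ``p_out`` otherwise, and — crucially — the cluster
also drives the observable similarities. Drugs of one cluster are
decorated variants of one scaffold family (so Morgan/Tanimoto drug-drug
similarity is higher within clusters), and targets of one cluster share
a sequence motif planted into random background (so Smith-Waterman
target-target similarity is higher within clusters). Similarity edges
therefore carry genuine signal about unobserved interactions, mirroring
the homology rationale behind similarity-based interaction networks.

All generators are byte-for-byte reproducible from one seed and emit the
same formats the real pipeline reads (SMILES CSV, FASTA, pair TSV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .prot_graph import STANDARD_AMINO_ACIDS

#: One core scaffold per drug cluster (diol, toluene, amide, amine, ether,
#: cresol, propanamide, tertiary amine); members decorate their cluster's
#: core with random alkyl substituents, so Morgan-fingerprint similarity
#: is high within a cluster and low across. Cores start and end with chain
#: atoms so decoration keeps them parseable.
FAMILY_CORES: tuple[str, ...] = (
    "OCCCO", "Cc1ccccc1", "CC(=O)NCC", "CCNCC",
    "CCOCC", "Oc1ccc(C)cc1", "CCC(=O)NC", "CN(C)CC",
)
ALKYL_DECORATIONS: tuple[str, ...] = ("", "C", "CC", "CCC", "C(C)C")

AA = np.array(list(STANDARD_AMINO_ACIDS))
#: Per-site substitution rate applied to each cluster member's copy of the
#: ancestral sequence (~15% divergence from the ancestor, a realistic
#: within-family distance that keeps local-alignment similarity high).
MUTATION_RATE = 0.15


@dataclass
class PlantedWorld:
    """Study conditions of the synthetic benchmark.

    Defaults are the standard conditions used throughout the test
    harness: 200 drugs x 100 targets in 4 clusters with within-cluster
    interaction probability 0.5 and across-cluster probability 0.02,
    balanced negatives.
    """

    n_drugs: int = 200
    n_targets: int = 100
    n_clusters: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    seed: int = 0
    length_range: tuple[int, int] = (60, 100)
    negative_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if min(self.n_drugs, self.n_targets, self.n_clusters) < 1:
            raise ValueError("n_drugs, n_targets, n_clusters must be positive")
        if self.length_range[0] < 5:
            raise ValueError("sequence lengths must be >= 5")


def cluster_of(index: int, n_clusters: int) -> int:
    """Deterministic round-robin cluster assignment shared by all generators."""
    return index % n_clusters


def generate_toy_smiles(n: int, seed: int = 0, n_clusters: int = 4) -> pd.DataFrame:
    """n parseable SMILES records with cluster-tied scaffold families.

    Returns columns (drug_id, smiles, cluster). Each record is its
    cluster's core scaffold with random alkyl decoration; every emitted
    SMILES parses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cluster = cluster_of(i, n_clusters)
        core = FAMILY_CORES[cluster % len(FAMILY_CORES)]
        smiles = ("C" * rng.integers(0, 3) + core
                  + ALKYL_DECORATIONS[rng.integers(len(ALKYL_DECORATIONS))])
        if Chem.MolFromSmiles(smiles) is None:  # decoration never breaks these, but be safe
            smiles = core
        rows.append({"drug_id": f"D{i:04d}", "smiles": smiles, "cluster": cluster})
    return pd.DataFrame(rows)


def generate_toy_sequences(n: int, length_range: tuple[int, int] = (60, 100),
                           seed: int = 0, n_clusters: int = 4) -> pd.DataFrame:
    """n protein sequences forming per-cluster homologous families.

    Returns columns (target_id, sequence, cluster). Each cluster has a
    random ancestral sequence; every member is a prefix of random length
    point-mutated at ~15% per site, so within-cluster local-alignment
    similarity is high and across-cluster similarity is background noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 5 or hi < lo:
        raise ValueError("length_range must satisfy 5 <= lo <= hi")
    rng = np.random.default_rng(seed)
    ancestors = [rng.choice(AA, size=hi) for _ in range(n_clusters)]
    rows = []
    for i in range(n):
        cluster = cluster_of(i, n_clusters)
        length = int(rng.integers(lo, hi + 1))
        seq = ancestors[cluster][:length].copy()
        mutate = rng.random(length) < MUTATION_RATE
        seq[mutate] = rng.choice(AA, size=int(mutate.sum()))
        rows.append({"target_id": f"T{i:04d}", "sequence": "".join(seq), "cluster": cluster})
    return pd.DataFrame(rows)


def generate_interactions(world: PlantedWorld) -> pd.DataFrame:
    """Labelled pairs from the planted cluster model.

    Every (drug, target) pair is positive with probability ``p_in`` if
    the entities share a cluster and ``p_out`` otherwise; negatives are
    sampled without replacement from the remaining pairs at
    ``negative_ratio`` times the positive count. Raises if no positive
    is drawn (use a different seed or larger world).
    """
    rng = np.random.default_rng(np.random.SeedSequence((world.seed, 2)))
    d_cl = np.array([cluster_of(i, world.n_clusters) for i in range(world.n_drugs)])
    t_cl = np.array([cluster_of(j, world.n_clusters) for j in range(world.n_targets)])
    same = d_cl[:, None] == t_cl[None, :]
    prob = np.where(same, world.p_in, world.p_out)
    positive = rng.random(prob.shape) < prob
    pos_d, pos_t = np.nonzero(positive)
    if len(pos_d) == 0:
        raise ValueError("no positive interactions drawn; re-seed or enlarge the world")
    neg_d, neg_t = np.nonzero(~positive)
    n_neg = int(round(world.negative_ratio * len(pos_d)))
    if n_neg > len(neg_d):
        raise ValueError("not enough non-interacting pairs to sample negatives")
    pick = rng.choice(len(neg_d), size=n_neg, replace=False)
    rows = [
        {"drug_id": f"D{i:04d}", "target_id": f"T{j:04d}", "label": 1}
        for i, j in zip(pos_d, pos_t)
    ] + [
        {"drug_id": f"D{neg_d[k]:04d}", "target_id": f"T{neg_t[k]:04d}", "label": 0}
        for k in np.sort(pick)
    ]
    return pd.DataFrame(rows)


def generate_world(world: PlantedWorld) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drugs, targets and labelled pairs for one planted world."""
    ss = np.random.SeedSequence(world.seed)
    s_drug, s_seq = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))
    drugs = generate_toy_smiles(world.n_drugs, seed=s_drug, n_clusters=world.n_clusters)
    targets = generate_toy_sequences(world.n_targets, world.length_range,
                                     seed=s_seq, n_clusters=world.n_clusters)
    pairs = generate_interactions(world)
    return drugs, targets, pairs
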