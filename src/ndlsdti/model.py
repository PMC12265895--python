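"""High-level modelling interface.

:class:`DTIModel` bundles the data (drug SMILES, target sequences,
labelled interaction pairs) with the pipeline configuration; ``fit``
runs the whole pipeline on a train/test split and returns a
:class:`DTIResults` carrying predictions, evaluation metrics, the
smoothing diagnostics and a ``summary()`` table; ``cross_validate``
repeats this over stratified folds. Pipeline stages, in order:

1. featurize — SMILES to molecular graphs, sequences to chain graphs;
2. encode — joint GCN training on the training pairs, 128-dim
   embeddings for every entity (or frozen random weights);
3. similarity edges — Tanimoto drug-drug and Smith-Waterman
   target-target edges (label-free, hence shared across folds);
4. assemble — heterogeneous graph whose dt edges come from the
   training positives only (test interactions never propagate);
5. smooth — node-dependent local smoothing (or a fixed depth);
6. classify — gradient-boosted trees on concatenated pair embeddings.

Edge-type ablations (``graph_variant``) and the fixed-depth baseline
(``fixed_depth``) reuse every cached stage, so sweeping variants over
one world is cheap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as io_mod
from .chem_graph import parse_smiles_table
from .gcn_encoder import EncoderConfig, GCNEncoder, embed_all, train_encoders
from .hetgraph import (HeteroGraph, SimilarityConfig, assemble_hetgraph,
                       build_similarity_edges, drug_similarity_matrix,
                       target_similarity_matrix)
from .ndls import NdlsConfig, NdlsProfile, ndls_profile
from .predict import (CVResults, MetricsReport, confusion_metrics, cross_validate,
                      fit_gbdt, pair_matrix, predict_scores, validate_pairs)

logger = logging.getLogger(__name__)

GRAPH_VARIANTS = ("full", "no_dd", "no_tt", "no_both")


def stage_seed(seed: int, stage: int) -> int:
    """Fan one global seed out to independent, reproducible per-stage seeds."""
    return int(np.random.SeedSequence((seed, stage)).generate_state(1)[0] % (2**31 - 1))


@dataclass
class DTIResults:
    """Outcome of one fitted train/test split."""

    metrics: Optional[MetricsReport]
    predictions: Optional[pd.DataFrame]   # drug_id, target_id, score, label
    profile: NdlsProfile
    graph: HeteroGraph
    dt_edges: set                          # (drug_id, target_id) used in propagation
    graph_variant: str
    fixed_depth: Optional[int]
    n_train: int
    n_test: int
    train_index: np.ndarray
    test_index: np.ndarray
    gbdt: object
    drug_encoder: GCNEncoder
    target_encoder: GCNEncoder
    fold: Optional[int] = None

    def summary(self) -> str:
        g = self.graph
        lsi = self.profile.lsi
        lines = [
            "Drug-target interaction model (NDLS heterogeneous graph + GBDT)",
            "=" * 64,
            f"nodes: {g.n_nodes} ({int(np.sum(g.node_types == 'drug'))} drugs, "
            f"{int(np.sum(g.node_types == 'target'))} targets)",
            f"edges: dd={g.n_edges('dd')}  tt={g.n_edges('tt')}  dt={g.n_edges('dt')}"
            f"   [variant: {self.graph_variant}]",
            (f"smoothing: fixed depth K={self.fixed_depth}" if self.fixed_depth is not None
             else f"smoothing: adaptive, K in [{lsi.min()}, {lsi.max()}], "
                  f"median {int(np.median(lsi))}"),
            f"pairs: {self.n_train} train / {self.n_test} test",
        ]
        if self.metrics is not None:
            m = self.metrics.to_dict()
            lines.append("-" * 64)
            lines.append("held-out metrics (threshold %.2f):" % self.metrics.threshold)
            for key in ("auc", "aupr", "f1", "sensitivity", "specificity", "precision"):
                val = m[key]
                lines.append(f"  {key:<12s}{'   n/a' if val is None else f'{val:8.4f}'}")
        return "\n".join(lines)


class DTIModel:
    """Drug-target interaction model over a heterogeneous similarity graph.

    Parameters
    ----------
    drugs : DataFrame with columns (drug_id, smiles)
    targets : DataFrame with columns (target_id, sequence)
    interactions : DataFrame with columns (drug_id, target_id, label)
        Binary labels; no duplicate pairs.
    encoder_config, similarity_config, ndls_config : stage settings
        Defaults reproduce the standard pipeline (2-layer GCN, 128-dim
        embeddings, Morgan/Tanimoto + Smith-Waterman edges at threshold
        0.5 with mutual top-5, epsilon = 0.05 smoothing).
    gbdt_params : dict, optional
        Overrides for the LightGBM classifier.
    encoder_mode : "trained" or "random"
        Joint link-prediction training of the encoders, or frozen random
        weights (fast; similarity + graph structure only).
    remove_test_dt : bool
        Keep test interactions out of the propagation graph (leakage
        control; switchable for comparison).
    seed : int
        Single source of randomness; fans out to per-stage seeds.
    """

    def __init__(self, drugs: pd.DataFrame, targets: pd.DataFrame,
                 interactions: pd.DataFrame, *,
                 encoder_config: EncoderConfig | None = None,
                 similarity_config: SimilarityConfig | None = None,
                 ndls_config: NdlsConfig | None = None,
                 gbdt_params: dict | None = None,
                 encoder_mode: str = "trained",
                 remove_test_dt: bool = True,
                 seed: int = 0):
        self.drugs = drugs.reset_index(drop=True)
        self.targets = targets.reset_index(drop=True)
        self.interactions = validate_pairs(interactions.reset_index(drop=True))
        known_d = set(self.drugs["drug_id"])
        known_t = set(self.targets["target_id"])
        stray = (set(self.interactions["drug_id"]) - known_d) | \
                (set(self.interactions["target_id"]) - known_t)
        if stray:
            raise KeyError(f"interaction entities without records: {sorted(stray)[:5]}")
        self.encoder_config = encoder_config or EncoderConfig()
        self.similarity_config = similarity_config or SimilarityConfig()
        self.ndls_config = ndls_config or NdlsConfig()
        self.gbdt_params = gbdt_params or {}
        if encoder_mode not in ("trained", "random"):
            raise ValueError("encoder_mode must be 'trained' or 'random'")
        self.encoder_mode = encoder_mode
        self.remove_test_dt = remove_test_dt
        self.seed = seed
        self._drug_graphs = None
        self._target_graphs = None
        self._S_dd = None
        self._S_tt = None

    # -- constructors -------------------------------------------------
    @classmethod
    def from_files(cls, smiles_csv: str | Path, fasta: str | Path,
                   pairs_tsv: str | Path, **kwargs) -> "DTIModel":
        return cls(io_mod.read_smiles_csv(smiles_csv),
                   io_mod.read_fasta(fasta),
                   io_mod.read_pairs_tsv(pairs_tsv), **kwargs)

    # -- cached featurization / similarity ----------------------------
    @property
    def drug_graphs(self) -> dict:
        if self._drug_graphs is None:
            self._drug_graphs = parse_smiles_table(
                list(zip(self.drugs["drug_id"], self.drugs["smiles"])))
        return self._drug_graphs

    @property
    def target_graphs(self) -> dict:
        if self._target_graphs is None:
            from .prot_graph import encode_sequence_table
            self._target_graphs = encode_sequence_table(
                list(zip(self.targets["target_id"], self.targets["sequence"])))
        return self._target_graphs

    @property
    def drug_similarity(self) -> pd.DataFrame:
        if self._S_dd is None:
            smiles = dict(zip(self.drugs["drug_id"], self.drugs["smiles"]))
            self._S_dd = drug_similarity_matrix(smiles, self.similarity_config)
        return self._S_dd

    @property
    def target_similarity(self) -> pd.DataFrame:
        if self._S_tt is None:
            seqs = {t.target_id: t.sequence for t in self.target_graphs.values()}
            self._S_tt = target_similarity_matrix(seqs, self.similarity_config)
        return self._S_tt

    def similarity_edges(self, graph_variant: str = "full") -> dict:
        """dd/tt edge lists for a graph variant (label-free, split-independent)."""
        if graph_variant not in GRAPH_VARIANTS:
            raise ValueError(f"graph_variant must be one of {GRAPH_VARIANTS}")
        cfg = self.similarity_config
        dd = tt = []
        if graph_variant in ("full", "no_tt"):
            dd = build_similarity_edges(self.drug_similarity, cfg.dd_threshold, cfg.topk)
        if graph_variant in ("full", "no_dd"):
            tt = build_similarity_edges(self.target_similarity, cfg.tt_threshold, cfg.topk)
        return {"dd": dd, "tt": tt}

    # -- fitting ------------------------------------------------------
    def fit_split(self, train_index, test_index, graph_variant: str = "full",
                  fixed_depth: int | None = None) -> DTIResults:
        """Run the full pipeline with an explicit train/test pair split."""
        train_index = np.asarray(train_index)
        test_index = np.asarray(test_index)
        pairs = self.interactions
        train_df = pairs.iloc[train_index]
        test_df = pairs.iloc[test_index]

        # 1-2: encoders + embeddings for every entity
        t0 = time.perf_counter()
        enc_seed = stage_seed(self.seed, 0)
        if self.encoder_mode == "trained":
            cfg = EncoderConfig(**{**self.encoder_config.__dict__, "seed": enc_seed})
            trained = train_encoders(
                list(train_df[["drug_id", "target_id", "label"]]
                     .itertuples(index=False, name=None)),
                self.drug_graphs, self.target_graphs, cfg)
            d_enc, t_enc = trained.drug_encoder, trained.target_encoder
        else:
            cfg = self.encoder_config
            d_enc = GCNEncoder.random(cfg, input_dim=5, seed=enc_seed)
            t_enc = GCNEncoder.random(cfg, input_dim=cfg.residue_embed_dim,
                                      embed_vocab=cfg.residue_vocab, seed=enc_seed + 1)
        Zd = embed_all(d_enc, self.drug_graphs)
        Zt = embed_all(t_enc, self.target_graphs)
        logger.info("encode: %d drugs + %d targets embedded (%.1fs, mode=%s)",
                    len(Zd), len(Zt), time.perf_counter() - t0, self.encoder_mode)

        # 3-4: heterogeneous graph; dt edges from training positives only
        t0 = time.perf_counter()
        sim = self.similarity_edges(graph_variant)
        dt = [tuple(p) for p in
              train_df.loc[train_df["label"] == 1, ["drug_id", "target_id"]].itertuples(
                  index=False, name=None)]
        if not self.remove_test_dt:
            dt += [tuple(p) for p in
                   test_df.loc[test_df["label"] == 1, ["drug_id", "target_id"]].itertuples(
                       index=False, name=None)]
        graph = assemble_hetgraph(Zd, Zt, sim["dd"], sim["tt"], dt)
        logger.info("assemble[%s]: %d nodes, dd=%d tt=%d dt=%d (%.1fs)",
                    graph_variant, graph.n_nodes, graph.n_edges("dd"),
                    graph.n_edges("tt"), graph.n_edges("dt"), time.perf_counter() - t0)

        # 5: node-dependent (or fixed-depth) smoothing
        t0 = time.perf_counter()
        profile = ndls_profile(graph, self.ndls_config, fixed_depth=fixed_depth)
        emb = profile.embeddings()
        logger.info("smooth: K in [%d, %d] (%.1fs)", profile.lsi.min(),
                    profile.lsi.max(), time.perf_counter() - t0)

        # 6: boosted-tree pair classifier
        t0 = time.perf_counter()
        gbdt = fit_gbdt(pair_matrix(emb, train_df), train_df["label"].to_numpy(),
                        self.gbdt_params, seed=stage_seed(self.seed, 1))
        logger.info("classify: %d train / %d test pairs (%.1fs)",
                    len(train_df), len(test_df), time.perf_counter() - t0)
        metrics = None
        predictions = None
        if len(test_df):
            scores = predict_scores(gbdt, pair_matrix(emb, test_df))
            metrics = confusion_metrics(test_df["label"].to_numpy(), scores)
            predictions = test_df.assign(score=scores)[
                ["drug_id", "target_id", "score", "label"]].reset_index(drop=True)

        return DTIResults(
            metrics=metrics, predictions=predictions, profile=profile, graph=graph,
            dt_edges=graph.dt_pairs(), graph_variant=graph_variant,
            fixed_depth=fixed_depth, n_train=len(train_df), n_test=len(test_df),
            train_index=train_index, test_index=test_index, gbdt=gbdt,
            drug_encoder=d_enc, target_encoder=t_enc)

    def fit(self, test_size: float = 0.2, graph_variant: str = "full",
            fixed_depth: int | None = None, split_seed: int | None = None) -> DTIResults:
        """Stratified random train/test split, then the full pipeline.

        ``test_size = 0`` trains on all pairs (no held-out metrics).
        """
        n = len(self.interactions)
        labels = self.interactions["label"].to_numpy()
        if test_size == 0:
            return self.fit_split(np.arange(n), np.array([], dtype=int),
                                  graph_variant, fixed_depth)
        from sklearn.model_selection import train_test_split
        tr, te = train_test_split(
            np.arange(n), test_size=test_size, stratify=labels,
            random_state=stage_seed(self.seed, 2) if split_seed is None else split_seed)
        return self.fit_split(tr, te, graph_variant, fixed_depth)

    def cross_validate(self, folds: int = 10, **fit_kwargs) -> CVResults:
        """Stratified k-fold CV; every fold refits the whole pipeline."""
        return cross_validate(self, folds=folds, seed=stage_seed(self.seed, 3), **fit_kwargs)
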