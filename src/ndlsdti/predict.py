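"""Pair scoring with gradient-boosted trees, metrics, and the CV protocol.

A candidate pair is represented by concatenating the smoothed drug and
target embeddings (drug block first; 256 coordinates under the default
128-dim embeddings) and scored by a LightGBM binary classifier. Count
metrics (sensitivity, specificity, precision, F1) are taken at a fixed
threshold; AUC and AUPR are threshold-free. Cross-validation is
pair-level and stratified, and inside every fold the propagation graph's
dt edges are rebuilt from that fold's training positives only, so test
interactions never leak into feature propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

PAIR_COLUMNS = ("drug_id", "target_id", "label")

#: Boosting defaults (the interaction classifier; all overridable).
DEFAULT_GBDT = dict(
    n_estimators=500,
    max_depth=6,
    num_leaves=63,
    learning_rate=0.05,
    subsample=0.8,
    subsample_freq=1,
    min_child_samples=20,
    max_bin=127,
    deterministic=True,
    force_row_wise=True,
    n_jobs=1,
    verbosity=-1,
)


def validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Check an interaction table: required columns, binary labels, no duplicates."""
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"interaction table missing columns {missing}")
    if not pairs["label"].isin((0, 1)).all():
        bad = pairs.loc[~pairs["label"].isin((0, 1))].index[0]
        raise ValueError(f"non-binary label at row {bad}")
    dup = pairs.duplicated(subset=["drug_id", "target_id"])
    if dup.any():
        d, t = pairs.loc[dup.idxmax(), ["drug_id", "target_id"]]
        raise ValueError(f"duplicate pair ({d!r}, {t!r})")
    return pairs


def pair_embedding(embeddings: pd.DataFrame, drug_id: str, target_id: str) -> np.ndarray:
    """Joint feature vector [X_drug || X_target]; drug block always first."""
    for eid in (drug_id, target_id):
        if eid not in embeddings.index:
            raise KeyError(f"entity {eid!r} has no embedding row")
    return np.concatenate([embeddings.loc[drug_id].to_numpy(float),
                           embeddings.loc[target_id].to_numpy(float)])


def pair_matrix(embeddings: pd.DataFrame, pairs: pd.DataFrame) -> np.ndarray:
    """Stack pair embeddings for every row of an interaction table."""
    for col in ("drug_id", "target_id"):
        missing = set(pairs[col]) - set(embeddings.index)
        if missing:
            raise KeyError(f"entities without embeddings: {sorted(missing)[:5]}")
    left = embeddings.loc[pairs["drug_id"]].to_numpy(float)
    right = embeddings.loc[pairs["target_id"]].to_numpy(float)
    return np.hstack([left, right])


def fit_gbdt(EMB: np.ndarray, labels: np.ndarray,
             params: dict | None = None, seed: int = 0) -> LGBMClassifier:
    """Fit the boosted-tree pair classifier on binary log-loss."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("GBDT training requires both classes")
    kwargs = dict(DEFAULT_GBDT)
    kwargs.update(params or {})
    model = LGBMClassifier(random_state=seed, **kwargs)
    model.fit(np.asarray(EMB, dtype=float), labels)
    return model


def predict_scores(model: LGBMClassifier, EMB_test: np.ndarray) -> np.ndarray:
    """Interaction likelihoods R in [0, 1], aligned with the test rows."""
    EMB_test = np.asarray(EMB_test, dtype=float)
    if EMB_test.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature width {EMB_test.shape[1]} != model width {model.n_features_in_}")
    import warnings

    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper records placeholder feature names even
        # for plain arrays; sklearn then warns on every array-input predict
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        return model.predict_proba(EMB_test)[:, 1]


@dataclass
class MetricsReport:
    """Confusion counts at a threshold plus threshold-free AUC/AUPR.

    Ratios with a zero denominator (and AUC/AUPR on single-class inputs)
    are reported as None rather than 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    auc: Optional[float]
    aupr: Optional[float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "n": self.n, "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "threshold": self.threshold, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1, "auc": self.auc, "aupr": self.aupr,
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def confusion_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Evaluate scored pairs: counts at ``threshold``, AUC/AUPR from ranks."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    both_classes = 0 < pos.sum() < labels.size
    auc = float(roc_auc_score(labels, scores)) if both_classes else None
    aupr = float(average_precision_score(labels, scores)) if both_classes else None
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold,
                         sensitivity=sens, specificity=spec, precision=prec,
                         f1=f1, auc=auc, aupr=aupr)


def make_imbalanced(pairs: pd.DataFrame, ratio: int = 10, seed: int = 0,
                    candidate_negatives: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a positives:negatives = 1:ratio interaction set.

    All positives are kept; exactly ``ratio * n_positives`` negatives are
    sampled without replacement from the table's own negatives plus any
    ``candidate_negatives`` (extra label-0 pairs, e.g. drawn from the
    unobserved cross product). Raises if the pool is too small.
    Deterministic given ``seed``.
    """
    validate_pairs(pairs)
    pos = pairs[pairs["label"] == 1]
    neg = pairs[pairs["label"] == 0]
    if candidate_negatives is not None:
        extra = candidate_negatives.copy()
        extra["label"] = 0
        neg = pd.concat([neg, extra[list(PAIR_COLUMNS)]], ignore_index=True)
        neg = neg.drop_duplicates(subset=["drug_id", "target_id"])
        pos_keys = set(zip(pos["drug_id"], pos["target_id"]))
        mask = [(d, t) not in pos_keys for d, t in zip(neg["drug_id"], neg["target_id"])]
        neg = neg[mask]
    n_needed = ratio * len(pos)
    if len(neg) < n_needed:
        raise ValueError(f"need {n_needed} negatives but only {len(neg)} candidates available")
    neg = neg.sort_values(["drug_id", "target_id"]).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(neg), size=n_needed, replace=False)
    out = pd.concat([pos, neg.iloc[np.sort(pick)]], ignore_index=True)
    return out[list(PAIR_COLUMNS)].reset_index(drop=True)


@dataclass
class CVResults:
    """Per-fold reports plus mean and standard deviation per metric."""

    fold_results: list  # list of DTIResults (one per fold)

    _METRICS = ("auc", "aupr", "f1", "sensitivity", "specificity", "precision")

    def metric_frame(self) -> pd.DataFrame:
        rows = []
        for k, res in enumerate(self.fold_results):
            d = res.metrics.to_dict()
            rows.append({"fold": k, **{m: d[m] for m in self._METRICS}})
        return pd.DataFrame(rows).set_index("fold")

    def mean(self) -> pd.Series:
        return self.metric_frame().mean()

    def std(self) -> pd.Series:
        return self.metric_frame().std()

    def summary(self) -> str:
        mf = self.metric_frame()
        lines = [f"{len(mf)}-fold cross-validation (pair-level stratified splits)",
                 "metric      mean     sd"]
        for m in self._METRICS:
            lines.append(f"{m:<11s}{mf[m].mean():7.4f}  {mf[m].std():.4f}")
        return "\n".join(lines)


def cross_validate(model, folds: int = 10, seed: int = 0, **fit_kwargs) -> CVResults:
    """Pair-level stratified k-fold evaluation of a DTIModel.

    Every fold refits the whole pipeline — encoders, similarity graph
    assembly with dt edges from that fold's training positives only,
    smoothing and the classifier — so no test interaction influences
    propagation (leakage control). ``model`` only needs the DTIModel
    split-fitting interface.
    """
    pairs = model.interactions
    labels = pairs["label"].to_numpy()
    if min(np.sum(labels == 1), np.sum(labels == 0)) < folds:
        raise ValueError(f"need at least {folds} pairs of each class for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results = []
    for k, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        res = model.fit_split(train_idx, test_idx, **fit_kwargs)
        res.fold = k
        results.append(res)
    return CVResults(fold_results=results)
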