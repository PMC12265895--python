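"""Readers and writers for the pipeline's plain-text formats.

Inputs: SMILES tables (two-column CSV ``drug_id,smiles`` or one SMILES
per line), protein FASTA (record id becomes the target id), and
interaction TSV (``drug_id<TAB>target_id<TAB>label``). Outputs:
prediction TSV, metrics JSON, and embedding/NDLS-profile tables.
Malformed records are reported with their line or record identifier.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .predict import PAIR_COLUMNS, validate_pairs
from .prot_graph import normalize_sequence


def read_smiles_csv(path: str | Path) -> pd.DataFrame:
    """Read a drug table: CSV with (drug_id, smiles) columns, or, if the
    file has a single column, one SMILES per line with generated ids."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if "smiles" in cols and ("drug_id" in cols or "id" in cols):
        df.columns = cols
        df = df.rename(columns={"id": "drug_id"})
    elif len(df.columns) == 1:
        smiles = pd.read_csv(path, header=None, dtype=str)[0]
        df = pd.DataFrame({"drug_id": [f"D{i:04d}" for i in range(len(smiles))],
                           "smiles": smiles})
    else:
        raise ValueError(f"{path}: expected columns (drug_id, smiles)")
    if df["drug_id"].duplicated().any():
        dup = df.loc[df["drug_id"].duplicated(), "drug_id"].iloc[0]
        raise ValueError(f"{path}: duplicate drug id {dup!r}")
    return df[["drug_id", "smiles"]]


def write_smiles_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[["drug_id", "smiles"]].to_csv(path, index=False)


def read_fasta(path: str | Path) -> pd.DataFrame:
    """Read a multi-record FASTA into (target_id, sequence) rows.

    Sequences are uppercased; gaps and '*' terminators are stripped.
    """
    path = Path(path)
    rows = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate target id {rec.id!r}")
        seen.add(rec.id)
        rows.append({"target_id": rec.id, "sequence": normalize_sequence(str(rec.seq))})
    if not rows:
        raise ValueError(f"{path}: no FASTA records found")
    return pd.DataFrame(rows)


def write_fasta(df: pd.DataFrame, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(f">{row['target_id']}\n")
            seq = row["sequence"]
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


def read_pairs_tsv(path: str | Path) -> pd.DataFrame:
    """Read labelled interaction pairs; labels must be 0/1."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["label"].isin((0, 1))
    if bad.any():
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-binary label on line {int(np.flatnonzero(bad)[0]) + 2}")
    try:
        return validate_pairs(df[list(PAIR_COLUMNS)])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_pairs_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[list(PAIR_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_predictions_tsv(predictions: pd.DataFrame, path: str | Path) -> None:
    """Write (drug_id, target_id, score, label) rows."""
    predictions[["drug_id", "target_id", "score", "label"]].to_csv(path, sep="\t", index=False)


def read_predictions_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    missing = [c for c in ("drug_id", "target_id", "score", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_metrics_json(metrics: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_embeddings_tsv(embeddings: pd.DataFrame, path: str | Path) -> None:
    embeddings.to_csv(path, sep="\t", index_label="entity_id")


def read_embeddings_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="entity_id")


def write_similarity_edges_tsv(edges: dict[str, list[tuple[str, str, float]]],
                               path: str | Path) -> None:
    """Similarity edges as (id_a, id_b, type, weight) rows."""
    rows = [
        {"id_a": a, "id_b": b, "type": etype, "weight": w}
        for etype, triples in edges.items()
        for a, b, w in triples
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "type", "weight"]).to_csv(
        path, sep="\t", index=False)
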