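"""Delimited-text I/O for feature tables and run artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nnclust.core import DataMatrix, normalize_matrix

__all__ = ["load_feature_table", "write_assignment", "write_summary", "file_sha256"]


def load_feature_table(
    path: str | Path,
    labels_col: str | None = None,
    normalize: str = "zscore",
):
    """Read a CSV/TSV feature table into a normalized DataMatrix.

    The delimiter is sniffed from the extension (.tsv/.txt -> tab, else
    comma). A column named ``id`` (case-insensitive, first column only) is
    used as sample identifiers; otherwise identifiers are 0-based row
    numbers. ``labels_col``, if given, is removed from the features and
    returned as ground-truth labels.

    Returns ``(DataMatrix, ids, labels_or_None)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] < 1:
        raise ValueError(f"{path}: no data rows")

    if df.columns.size and df.columns[0].lower() == "id":
        ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    else:
        ids = [str(i) for i in range(df.shape[0])]

    labels = None
    if labels_col is not None:
        if labels_col not in df.columns:
            raise KeyError(f"label column {labels_col!r} not in {list(df.columns)}")
        labels = df[labels_col].to_numpy()
        df = df.drop(columns=[labels_col])

    if df.shape[1] < 1:
        raise ValueError(f"{path}: no feature columns remain")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        for col in bad:
            row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
            raise ValueError(f"non-numeric value in column {col!r}, row {row}")
    raw = df.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        r, c = np.argwhere(~np.isfinite(raw))[0]
        raise ValueError(f"missing/non-finite value at row {int(r)}, column {df.columns[int(c)]!r}")

    M = normalize_matrix(raw, method=normalize)
    M = DataMatrix(M.values, feature_names=tuple(df.columns))
    return M, ids, labels


def write_assignment(path: str | Path, ids, labels) -> None:
    """Write the (sample id, 0-based cluster) table as CSV."""
    pd.DataFrame({"id": ids, "cluster": np.asarray(labels)}).to_csv(path, index=False)


def write_summary(path: str | Path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
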