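"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are TSV (CSV auto-detected by extension) with the
feature id in the first column and sample ids in the header; labels are a
two-column table (sample_id, class in {0,1}); probe maps are two-column
(probe_id, gene_id). Models round-trip through JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bayesnet import BNModel
from .pipeline import EnsembleModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_labels",
    "read_probe_map",
    "write_matrix",
    "save_model",
    "load_model",
]


def _sep(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _check_unique(values, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what}: {v!r}")
        seen.add(v)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a features x samples matrix; validates ids and numeric cells."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))
    _check_unique(header[1:], "sample id")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    _check_unique(df.index, "feature id")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = coerced.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric cell at feature {row!r}, sample {col!r} in {path}"
            )
    df = df.astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"non-finite values in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_labels(path: str | Path) -> pd.Series:
    """Read per-sample binary labels (two columns: sample_id, class)."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample_id, class)")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(ids, "sample id")
    classes = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if classes.isna().any():
        row = ids[classes.isna()].iloc[0]
        raise ValueError(f"non-numeric class label for sample {row!r}")
    classes = classes.astype(int)
    if not set(classes.unique()) <= {0, 1}:
        raise ValueError("class labels must be 0 or 1")
    return pd.Series(classes.to_numpy(), index=pd.Index(ids), name="label")


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read probe->gene pairs; duplicate pairs are collapsed."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe_id, gene_id)")
    out = df.iloc[:, :2].astype(str)
    out.columns = ["probe_id", "gene_id"]
    return out.drop_duplicates().reset_index(drop=True)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep(path))


def save_model(model, path: str | Path) -> None:
    """Serialize an ensemble or single BN model to JSON (bit-stable)."""
    d = model.to_dict()
    if "type" not in d:
        d["type"] = "bn"
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)


def load_model(path: str | Path):
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("type", "ensemble")
    if kind == "ensemble":
        return EnsembleModel.from_dict(d)
    return BNModel.from_dict(d)
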