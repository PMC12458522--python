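"""Delimited-text readers and writers.

All on-disk formats are plain delimited text (comma or tab, auto-detected):

* time series — nodes as rows, timepoints as columns, optional header row
* connectome — square matrix, or long format with columns (i, j, value)
  using 1-based node indices
* phenotype — header required: subject_id, score, then covariate columns
* atlas — header required: node_index (1-based), network_name
* cohort directory — ``edges.tsv`` (subjects x E), ``phenotype.tsv``,
  ``meta.json``; floats are written with 17 significant digits so a
  write/read round trip is bit-exact
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CohortDataset,
    Connectome,
    NetworkAtlas,
    TimeSeriesMatrix,
    edge_count,
)

__all__ = [
    "read_time_series",
    "read_connectome",
    "read_phenotype",
    "read_atlas_labels",
    "write_cohort",
    "read_cohort",
]

_FLOAT_FMT = "%.17g"


def _sniff_sep(path: os.PathLike | str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_time_series(path: os.PathLike | str, subject_id: str | None = None) -> TimeSeriesMatrix:
    """Read a nodes x timepoints matrix; a non-numeric first row is a header."""
    sep = _sniff_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    header = 0 if any(not _is_number(tok) for tok in first.split(sep) if tok) else None
    frame = pd.read_csv(path, sep=sep, header=header, float_precision="round_trip")
    values = frame.to_numpy(dtype=float)
    sid = subject_id if subject_id is not None else Path(path).stem
    return TimeSeriesMatrix(subject_id=sid, values=values)


def read_connectome(path: os.PathLike | str, subject_id: str | None = None) -> Connectome:
    """Read one subject's z-matrix (square, or long (i, j, value) 1-based)."""
    sep = _sniff_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    tokens = [t for t in first.split(sep) if t]
    header = 0 if any(not _is_number(t) for t in tokens) else None
    frame = pd.read_csv(path, sep=sep, header=header, float_precision="round_trip")
    sid = subject_id if subject_id is not None else Path(path).stem

    if frame.shape[1] == 3 and frame.shape[0] != 3:
        return _connectome_from_long(frame, sid)
    values = frame.to_numpy(dtype=float)
    if values.shape[0] == values.shape[1]:
        return Connectome(subject_id=sid, z_matrix=values)
    if values.shape[1] == 3:
        return _connectome_from_long(frame, sid)
    raise ValueError(f"{path}: neither a square matrix nor a 3-column long format")


def _connectome_from_long(frame: pd.DataFrame, subject_id: str) -> Connectome:
    arr = frame.to_numpy(dtype=float)
    i = arr[:, 0].astype(int)
    j = arr[:, 1].astype(int)
    if np.any(i < 1) or np.any(j < 1):
        raise ValueError("long-format node indices must be 1-based positive integers")
    n = int(max(i.max(), j.max()))
    z = np.zeros((n, n))
    filled = np.zeros((n, n), dtype=bool)
    for a, b, v in zip(i - 1, j - 1, arr[:, 2]):
        if a == b:
            if v != 0.0:
                raise ValueError(f"nonzero diagonal entry at node {a + 1}")
            continue
        for x, y in ((a, b), (b, a)):
            if filled[x, y] and z[x, y] != v:
                raise ValueError(f"conflicting duplicate entry for pair ({a + 1}, {b + 1})")
            z[x, y] = v
            filled[x, y] = True
    return Connectome(subject_id=subject_id, z_matrix=z)


def read_phenotype(path: os.PathLike | str) -> pd.DataFrame:
    """Read the phenotype table; requires subject_id and score columns."""
    frame = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    for col in ("subject_id", "score"):
        if col not in frame.columns:
            raise ValueError(f"{path}: phenotype table lacks required column {col!r}")
    frame["subject_id"] = frame["subject_id"].astype(str)
    return frame


def read_atlas_labels(path: os.PathLike | str) -> NetworkAtlas:
    """Read a node_index -> network_name table; validates full 1..n coverage."""
    frame = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    for col in ("node_index", "network_name"):
        if col not in frame.columns:
            raise ValueError(f"{path}: atlas table lacks required column {col!r}")
    idx = frame["node_index"].to_numpy()
    try:
        idx = idx.astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-integer node_index") from exc
    n = len(frame)
    dup = frame.loc[frame["node_index"].duplicated(), "node_index"].tolist()
    if dup:
        lines = (frame.index[frame["node_index"].isin(dup)] + 2).tolist()
        raise ValueError(f"{path}: duplicate node_index {dup} (lines {lines})")
    missing = sorted(set(range(1, n + 1)) - set(idx.tolist()))
    if missing:
        raise ValueError(f"{path}: node_index not a complete 1..{n} range; missing {missing}")
    order = np.argsort(idx)
    labels = frame["network_name"].astype(str).to_numpy()[order]
    return NetworkAtlas(node_labels=tuple(labels))


def write_cohort(dataset: CohortDataset, directory: os.PathLike | str) -> Path:
    """Write a cohort to its on-disk directory layout; returns the directory."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "edges.tsv", dataset.edge_matrix, fmt=_FLOAT_FMT, delimiter="\t")
    pheno = pd.DataFrame({"subject_id": list(dataset.subject_ids), "score": dataset.score})
    for col in dataset.covariate_names:
        pheno[col] = dataset.covariates[col].to_numpy(dtype=float)
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = {
        "node_count": int(dataset.node_count),
        "n_subjects": int(dataset.n_subjects),
        "covariates": list(dataset.covariate_names),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return out


def read_cohort(directory: os.PathLike | str) -> CohortDataset:
    """Read a cohort directory written by :func:`write_cohort`."""
    src = Path(directory)
    meta = json.loads((src / "meta.json").read_text(encoding="utf-8"))
    edges = np.loadtxt(src / "edges.tsv", delimiter="\t", ndmin=2)
    pheno = read_phenotype(src / "phenotype.tsv")
    cov_cols: Sequence[str] = meta["covariates"]
    node_count = int(meta["node_count"])
    if edges.shape[1] != edge_count(node_count):
        raise ValueError(
            f"{src}: edges.tsv has {edges.shape[1]} columns, expected "
            f"{edge_count(node_count)} for {node_count} nodes"
        )
    return CohortDataset(
        edge_matrix=edges,
        score=pheno["score"].to_numpy(dtype=float),
        covariates=pheno.loc[:, list(cov_cols)].astype(float).reset_index(drop=True),
        subject_ids=tuple(pheno["subject_id"]),
        node_count=node_count,
    )
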