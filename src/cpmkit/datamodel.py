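"""Core data containers for connectome-based prediction.

A *connectome* is one subject's node-by-node matrix of functional
connectivity values: Fisher z-transformed Pearson correlations of regional
BOLD time courses. Each off-diagonal entry is an *edge* — the unit of
feature selection throughout the pipeline. A cohort stacks every subject's
vectorized edges into a subjects x edges matrix alongside the behavioral
score (e.g. SRS Total raw) and nuisance covariates (age in years, mean
framewise displacement in mm, optionally full-scale IQ).

The edge-ordering convention is fixed here and used by every downstream
module: the strict upper triangle in row-major order, i.e. edge k
enumerates node pairs (i, j) with 0-based i < j, ordered by increasing i
then increasing j. ``edge_pairs`` / ``edge_index`` expose the mapping in
both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CLIP_R",
    "TimeSeriesMatrix",
    "Connectome",
    "CohortDataset",
    "NetworkAtlas",
    "edge_count",
    "edge_pairs",
    "edge_index",
    "build_connectome",
    "vectorize_edges",
    "assemble_cohort",
]

#: correlations are clamped into [-DEFAULT_CLIP_R, DEFAULT_CLIP_R] before
#: atanh so duplicated signals degrade to a large finite z instead of inf
DEFAULT_CLIP_R = 1.0 - 1e-7

_SYMMETRY_ATOL = 1e-10


def edge_count(n_nodes: int) -> int:
    """Number of unordered node pairs, E = n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (i, j) of the node pair for every edge index, in edge order.

    Edge k corresponds to nodes ``(edge_pairs(n)[0][k], edge_pairs(n)[1][k])``.
    """
    return np.triu_indices(n_nodes, k=1)


def edge_index(i: int, j: int, n_nodes: int) -> int:
    """Edge index of the unordered node pair (i, j), 0-based."""
    if i == j:
        raise ValueError("self-pairs (i == j) are not edges")
    if i > j:
        i, j = j, i
    if not (0 <= i < j < n_nodes):
        raise ValueError(f"pair ({i}, {j}) out of range for {n_nodes} nodes")
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Per-subject node time courses (nodes x timepoints, arbitrary BOLD units)."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D nodes x timepoints array")
        if values.shape[1] < 3:
            raise ValueError(
                f"subject {self.subject_id!r}: {values.shape[1]} timepoints; "
                "at least 3 are required for a defined correlation"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite time-series values")
        constant = np.where(values.std(axis=1) == 0.0)[0]
        if constant.size:
            raise ValueError(
                f"subject {self.subject_id!r}: constant time course at node(s) "
                f"{constant.tolist()} (zero variance)"
            )
        object.__setattr__(self, "values", values)

    @property
    def node_count(self) -> int:
        return self.values.shape[0]

    @property
    def timepoint_count(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Connectome:
    """One subject's symmetric Fisher-z connectivity matrix (diagonal 0)."""

    subject_id: str
    z_matrix: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_matrix must be square")
        if not np.allclose(z, z.T, rtol=0.0, atol=_SYMMETRY_ATOL):
            raise ValueError(
                f"subject {self.subject_id!r}: z_matrix not symmetric within {_SYMMETRY_ATOL}"
            )
        if np.any(np.diagonal(z) != 0.0):
            raise ValueError(f"subject {self.subject_id!r}: diagonal must be exactly 0")
        off = z[~np.eye(z.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite off-diagonal entries")
        object.__setattr__(self, "z_matrix", z)

    @property
    def node_count(self) -> int:
        return self.z_matrix.shape[0]


@dataclass(frozen=True)
class NetworkAtlas:
    """Assignment of each parcellation node to one named functional network."""

    node_labels: tuple[str, ...]
    network_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.node_labels)
        if not labels:
            raise ValueError("atlas has no nodes")
        names = tuple(self.network_names)
        if not names:
            # first-appearance order keeps output stable for generated atlases
            seen: dict[str, None] = {}
            for lab in labels:
                seen.setdefault(lab, None)
            names = tuple(seen)
        if len(set(names)) != len(names):
            raise ValueError("duplicate network names")
        unknown = sorted(set(labels) - set(names))
        if unknown:
            raise ValueError(f"node labels not in network_names: {unknown}")
        object.__setattr__(self, "node_labels", labels)
        object.__setattr__(self, "network_names", names)

    @property
    def node_count(self) -> int:
        return len(self.node_labels)

    def label_codes(self) -> np.ndarray:
        """Per-node integer code into ``network_names``."""
        lut = {name: k for k, name in enumerate(self.network_names)}
        return np.array([lut[lab] for lab in self.node_labels], dtype=np.int64)


@dataclass
class CohortDataset:
    """Subjects x edges matrix with aligned behavioral score and covariates.

    ``covariates`` is a DataFrame whose columns are the named nuisance
    variables (canonically ``age`` and ``motion``); rows are aligned with
    ``edge_matrix``, ``score`` and ``subject_ids``.
    """

    edge_matrix: np.ndarray
    score: np.ndarray
    covariates: pd.DataFrame
    subject_ids: tuple[str, ...]
    node_count: int

    def __post_init__(self) -> None:
        self.edge_matrix = np.asarray(self.edge_matrix, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        n = self.edge_matrix.shape[0]
        if self.edge_matrix.ndim != 2:
            raise ValueError("edge_matrix must be 2-D (subjects x edges)")
        if len(self.score) != n or len(self.subject_ids) != n or len(self.covariates) != n:
            raise ValueError("edge_matrix, score, covariates and subject_ids must be aligned")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_id")
        if self.edge_matrix.shape[1] != edge_count(self.node_count):
            raise ValueError(
                f"edge_matrix has {self.edge_matrix.shape[1]} columns but "
                f"{self.node_count} nodes imply E = {edge_count(self.node_count)}"
            )
        if n > 0 and np.ptp(self.score) == 0.0:
            raise ValueError("behavioral score is constant; edge selection is undefined")
        cov = self.covariates.to_numpy(dtype=float) if len(self.covariates.columns) else None
        if cov is not None and not np.all(np.isfinite(cov)):
            bad = [
                c for c in self.covariates.columns
                if not np.all(np.isfinite(self.covariates[c].to_numpy(dtype=float)))
            ]
            raise ValueError(f"missing/non-finite covariate value in column(s) {bad}")

    @property
    def n_subjects(self) -> int:
        return self.edge_matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_matrix.shape[1]

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariates.columns)

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Covariate columns as a subjects x C float array (all columns by default)."""
        if names is None:
            names = self.covariate_names
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise KeyError(f"unknown covariate(s) {missing}; have {list(self.covariates.columns)}")
        return self.covariates.loc[:, list(names)].to_numpy(dtype=float)

    def subset(self, rows: np.ndarray) -> "CohortDataset":
        """New dataset restricted to the given row indices (order preserved)."""
        rows = np.asarray(rows)
        return CohortDataset(
            edge_matrix=self.edge_matrix[rows],
            score=self.score[rows],
            covariates=self.covariates.iloc[rows].reset_index(drop=True),
            subject_ids=tuple(self.subject_ids[i] for i in rows),
            node_count=self.node_count,
        )


def build_connectome(ts: TimeSeriesMatrix, clip_r: float = DEFAULT_CLIP_R) -> Connectome:
    """Pearson-correlate node time courses and Fisher z-transform.

    Off-diagonal entry (i, j) is atanh(r_ij) with r_ij clamped into
    [-clip_r, clip_r]; the diagonal is 0 by convention.
    """
    if not (0.0 < clip_r < 1.0):
        raise ValueError("clip_r must lie in (0, 1)")
    r = np.corrcoef(ts.values)
    np.clip(r, -clip_r, clip_r, out=r)
    z = np.arctanh(r)
    z = 0.5 * (z + z.T)  # corrcoef is symmetric up to rounding; enforce exactly
    np.fill_diagonal(z, 0.0)
    return Connectome(subject_id=ts.subject_id, z_matrix=z)


def vectorize_edges(c: Connectome) -> np.ndarray:
    """Strict upper triangle of the z-matrix in the package's fixed edge order."""
    iu = edge_pairs(c.node_count)
    return c.z_matrix[iu].copy()


def assemble_cohort(
    connectomes: Sequence[Connectome],
    phenotype_table: "pd.DataFrame | str",
) -> CohortDataset:
    """Join vectorized connectomes with a phenotype table into a cohort.

    The phenotype table must have columns ``subject_id``, ``score`` and at
    least one covariate column; subjects are ordered as in the table.
    Subjects present in only one source are an error — nothing is dropped
    silently.
    """
    if isinstance(phenotype_table, (str, bytes)) or hasattr(phenotype_table, "__fspath__"):
        from .io import read_phenotype

        table = read_phenotype(phenotype_table)
    else:
        table = phenotype_table.copy()
    required = {"subject_id", "score"}
    if not required <= set(table.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    table["subject_id"] = table["subject_id"].astype(str)
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in phenotype table: {dup}")

    by_id: dict[str, Connectome] = {}
    for c in connectomes:
        if c.subject_id in by_id:
            raise ValueError(f"duplicate connectome for subject {c.subject_id!r}")
        by_id[c.subject_id] = c
    if not by_id:
        raise ValueError("no connectomes supplied")

    node_counts = {c.node_count for c in by_id.values()}
    if len(node_counts) != 1:
        raise ValueError(f"node_count differs across subjects: {sorted(node_counts)}")
    (n_nodes,) = node_counts

    table_ids = list(table["subject_id"])
    missing_conn = [s for s in table_ids if s not in by_id]
    if missing_conn:
        raise ValueError(f"phenotype rows without a connectome: {missing_conn}")
    extra_conn = sorted(set(by_id) - set(table_ids))
    if extra_conn:
        raise ValueError(f"connectomes without a phenotype row: {extra_conn}")

    edges = np.stack([vectorize_edges(by_id[s]) for s in table_ids])
    cov_cols = [c for c in table.columns if c not in ("subject_id", "score")]
    covariates = table.loc[:, cov_cols].reset_index(drop=True).astype(float)
    return CohortDataset(
        edge_matrix=edges,
        score=table["score"].to_numpy(dtype=float),
        covariates=covariates,
        subject_ids=tuple(table_ids),
        node_count=n_nodes,
    )
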