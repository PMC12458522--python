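"""Synthetic multi-subject connectome cohorts with planted brain-behavior signal.

The generator emulates the statistical structure the CPM analysis assumes,
at the scale of the study it mirrors: a 268-node parcellation assigned to
10 canonical networks, cohorts of 352 (source) and 28 (target) subjects,
scores on the SRS Total raw scale, ages uniform over the cohorts' reported
ranges, and head motion (mean framewise displacement) Gamma-distributed
around 0.147 mm (SD 0.044 mm).

Generative model (direct-connectome mode, the default):

* baseline edge values are standard Gaussian with a common within-block
  factor giving correlation ``within_block_corr`` between edges that fall
  in the same network block;
* a per-subject latent trait t ~ N(0, 1) is added to the planted positive
  signal edges (+ signal_scale * t) and subtracted from the negative ones;
* the raw score is beta * t + sum(covariate_effects * covariate) +
  N(0, noise_sd), optionally confounded with motion, then affinely mapped
  to the requested score mean/SD (monotone, so rank-based evaluation is
  unaffected).

Time-series mode instead draws node time courses whose expected
correlations realize a damped version of the same target structure and
passes them through :func:`~cpmkit.datamodel.build_connectome`; sampling
noise at finite scan length attenuates the planted signal, which is the
point of that mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    CohortDataset,
    NetworkAtlas,
    TimeSeriesMatrix,
    build_connectome,
    edge_count,
    edge_pairs,
    vectorize_edges,
)

__all__ = [
    "NETWORK_NAMES",
    "SyntheticSpec",
    "GroundTruth",
    "default_atlas",
    "simulate_cohort",
    "simulate_cohort_pair",
]

#: the 10 canonical functional networks of the 268-node atlas
NETWORK_NAMES = ("CBL", "DMN", "FP", "Limb", "MF", "MOT", "SC", "VAs", "VI", "VII")


def default_atlas(n_nodes: int = 268, names: tuple[str, ...] = NETWORK_NAMES) -> NetworkAtlas:
    """Deterministic atlas assigning contiguous, near-equal blocks of nodes."""
    if n_nodes < len(names):
        names = names[:n_nodes]
    codes = (np.arange(n_nodes) * len(names)) // n_nodes
    return NetworkAtlas(
        node_labels=tuple(names[c] for c in codes), network_names=tuple(names)
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated cohort (defaults: source-cohort scale)."""

    n_subjects: int = 352
    n_nodes: int = 268
    atlas: NetworkAtlas | None = None
    n_timepoints: int | None = None          # None -> direct-connectome mode
    n_signal_pos: int = 128
    n_signal_neg: int = 214
    signal_edges_pos: tuple[int, ...] | None = None
    signal_edges_neg: tuple[int, ...] | None = None
    beta: float = 1.0                        # score units (of the raw scale) per unit t
    signal_scale: float = 0.5                # Fisher-z units added to a signal edge per unit t
    noise_sd: float = 0.5
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    motion_score_confound: float = 0.0       # raw-score units per SD of motion
    within_block_corr: float = 0.2
    score_mean: float = 43.7                 # SRS Total raw scale of the 352-subject cohort
    score_sd: float | None = 40.2            # None -> leave scores on the raw latent scale
    age_range: tuple[float, float] = (6.0, 15.0)
    motion_mean: float = 0.147               # mean framewise displacement, mm
    motion_sd: float = 0.044
    ts_corr_scale: float = 0.3               # damping of z targets in time-series mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.n_timepoints is not None and self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")

    @property
    def n_edges(self) -> int:
        return edge_count(self.n_nodes)

    def resolve(self) -> "SyntheticSpec":
        """Fill in the atlas and the planted edge sets, deterministically from seed."""
        atlas = self.atlas if self.atlas is not None else default_atlas(self.n_nodes)
        if atlas.node_count != self.n_nodes:
            raise ValueError("atlas node count differs from n_nodes")
        pos, neg = self.signal_edges_pos, self.signal_edges_neg
        if pos is None or neg is None:
            rng = np.random.default_rng([self.seed, 101])
            total = self.n_signal_pos + self.n_signal_neg
            if total > self.n_edges:
                raise ValueError("more signal edges requested than edges exist")
            chosen = rng.choice(self.n_edges, size=total, replace=False)
            pos = tuple(int(i) for i in np.sort(chosen[: self.n_signal_pos]))
            neg = tuple(int(i) for i in np.sort(chosen[self.n_signal_pos:]))
        else:
            pos = tuple(int(i) for i in pos)
            neg = tuple(int(i) for i in neg)
        if set(pos) & set(neg):
            raise ValueError("signal edge sets must be disjoint")
        if pos and max(pos) >= self.n_edges or neg and max(neg) >= self.n_edges:
            raise ValueError("signal edge index out of range")
        return replace(self, atlas=atlas, signal_edges_pos=pos, signal_edges_neg=neg)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: reproducible bit-for-bit from (spec, seed)."""

    spec: SyntheticSpec
    latent_trait: np.ndarray
    true_scores_linear_predictor: np.ndarray
    signal_edges_pos: tuple[int, ...]
    signal_edges_neg: tuple[int, ...]


def _edge_block_ids(atlas: NetworkAtlas) -> np.ndarray:
    codes = atlas.label_codes()
    iu, ju = edge_pairs(atlas.node_count)
    G = len(atlas.network_names)
    lo = np.minimum(codes[iu], codes[ju])
    hi = np.maximum(codes[iu], codes[ju])
    return lo * G + hi


def simulate_cohort(
    spec: SyntheticSpec,
    draw_seed: int | None = None,
    subject_prefix: str = "sub",
) -> tuple[CohortDataset, GroundTruth]:
    """Simulate one cohort; ``draw_seed`` overrides the subject-level draws only.

    The planted structure (atlas, signal edge sets) always derives from
    ``spec.seed``, so two cohorts simulated from the same spec with
    different draw seeds share their signal edges.
    """
    rspec = spec.resolve()
    seed = spec.seed if draw_seed is None else draw_seed
    rng = np.random.default_rng([seed, 202])
    n, E = rspec.n_subjects, rspec.n_edges
    atlas = rspec.atlas
    pos = np.asarray(rspec.signal_edges_pos, dtype=np.int64)
    neg = np.asarray(rspec.signal_edges_neg, dtype=np.int64)

    t = rng.standard_normal(n)
    rho = rspec.within_block_corr
    block_ids = _edge_block_ids(atlas)
    G = len(atlas.network_names)
    g = rng.standard_normal((n, G * G))
    eps = rng.standard_normal((n, E))
    edges = np.sqrt(1.0 - rho) * eps + np.sqrt(rho) * g[:, block_ids]
    if pos.size:
        edges[:, pos] += rspec.signal_scale * t[:, None]
    if neg.size:
        edges[:, neg] -= rspec.signal_scale * t[:, None]

    age = rng.uniform(*rspec.age_range, size=n)
    shape = (rspec.motion_mean / rspec.motion_sd) ** 2
    motion = rng.gamma(shape, rspec.motion_mean / shape, size=n)
    covariates = pd.DataFrame({"age": age, "motion": motion})

    raw = rspec.beta * t + rng.normal(0.0, rspec.noise_sd, size=n)
    var_raw = rspec.beta**2 + rspec.noise_sd**2
    mean_raw = 0.0
    cov_var = {
        "age": (rspec.age_range[1] - rspec.age_range[0]) ** 2 / 12.0,
        "motion": rspec.motion_sd**2,
    }
    cov_mean = {
        "age": 0.5 * (rspec.age_range[0] + rspec.age_range[1]),
        "motion": rspec.motion_mean,
    }
    for name, effect in rspec.covariate_effects.items():
        if name not in covariates.columns:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        raw = raw + effect * covariates[name].to_numpy()
        var_raw += effect**2 * cov_var[name]
        mean_raw += effect * cov_mean[name]
    if rspec.motion_score_confound:
        raw = raw + rspec.motion_score_confound * (motion - rspec.motion_mean) / rspec.motion_sd
        var_raw += rspec.motion_score_confound**2

    if rspec.score_sd is None:
        score = raw
    else:
        if var_raw == 0.0:
            raise ValueError("degenerate score: beta, noise_sd and effects all zero")
        score = rspec.score_mean + rspec.score_sd * (raw - mean_raw) / np.sqrt(var_raw)

    subject_ids = tuple(f"{subject_prefix}-{i + 1:04d}" for i in range(n))

    if rspec.n_timepoints is not None:
        edges = _edges_via_time_series(rspec, edges, subject_ids, rng)

    dataset = CohortDataset(
        edge_matrix=edges,
        score=score,
        covariates=covariates,
        subject_ids=subject_ids,
        node_count=rspec.n_nodes,
    )
    truth = GroundTruth(
        spec=rspec,
        latent_trait=t,
        true_scores_linear_predictor=raw,
        signal_edges_pos=rspec.signal_edges_pos,
        signal_edges_neg=rspec.signal_edges_neg,
    )
    return dataset, truth


def _edges_via_time_series(
    rspec: SyntheticSpec,
    target_z: np.ndarray,
    subject_ids: tuple[str, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Realize each subject's target edge structure through sampled time courses."""
    n_nodes = rspec.n_nodes
    iu = edge_pairs(n_nodes)
    out = np.empty_like(target_z)
    for s, sid in enumerate(subject_ids):
        r_target = np.tanh(rspec.ts_corr_scale * target_z[s])
        R = np.eye(n_nodes)
        R[iu] = r_target
        R = R + R.T - np.eye(n_nodes)
        # project to the nearest valid correlation matrix: clip eigenvalues,
        # rescale to unit diagonal
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 1e-4, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        L = np.linalg.cholesky(R + 1e-10 * np.eye(n_nodes))
        ts = L @ rng.standard_normal((n_nodes, rspec.n_timepoints))
        conn = build_connectome(TimeSeriesMatrix(subject_id=sid, values=ts))
        out[s] = vectorize_edges(conn)
    return out


def simulate_cohort_pair(
    spec: SyntheticSpec,
    seed_target: int,
    n_target: int = 28,
    target_score_mean: float = 55.1,
    target_score_sd: float = 32.0,
    target_age_range: tuple[float, float] = (4.0, 11.0),
    drop_target_signal: bool = False,
) -> tuple[CohortDataset, CohortDataset, GroundTruth]:
    """Two cohorts sharing planted signal edges but independent subject draws.

    The source follows ``spec`` (default 352 subjects, source-cohort score
    scale and age range); the target mirrors the smaller cohort (default 28
    subjects, its own score scale, younger ages). ``drop_target_signal``
    severs the edge-score link in the target (signal_scale = 0) while
    keeping everything else, for negative-control experiments.
    """
    rspec = spec.resolve()
    source, truth = simulate_cohort(rspec, subject_prefix="src")
    target_spec = replace(
        rspec,
        n_subjects=n_target,
        score_mean=target_score_mean,
        score_sd=None if rspec.score_sd is None else target_score_sd,
        age_range=target_age_range,
        signal_scale=0.0 if drop_target_signal else rspec.signal_scale,
    )
    target, _ = simulate_cohort(target_spec, draw_seed=seed_target, subject_prefix="tgt")
    return source, target, truth
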