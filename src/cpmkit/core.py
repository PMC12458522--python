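"""Connectome-based predictive modeling: selection, fitting, LOOCV.

The CPM procedure: correlate every edge with the behavioral score across
training subjects, keep edges passing a p-value threshold (positively and
negatively correlated edges form separate masks), sum each subject's
selected edges into positive/negative *network strengths*, regress the
score on each strength (ordinary least squares, one predictor plus
intercept), and predict held-out subjects from their strengths. Under
leave-one-subject-out cross-validation, selection and fitting are repeated
with each subject excluded in turn; the procedure is fully deterministic.

For the default plain-Pearson selection statistic, the per-fold edge-score
correlations are computed by an exact downdate of the full-sample sufficient
statistics (subtracting the held-out subject's contribution), which makes
all folds a handful of vectorized array operations. The partial-correlation
variant residualizes edges and score on the covariates per fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .datamodel import CohortDataset

__all__ = [
    "EdgeMask",
    "EdgeAssociation",
    "CPMModel",
    "FoldResult",
    "LoocvResult",
    "edge_behavior_association",
    "select_edges",
    "network_strength",
    "fit_cpm",
    "predict_cpm",
    "loocv_cpm",
]

logger = logging.getLogger(__name__)

COMBINED_RULES = ("sum_of_predictions", "two_predictor")
SIGNS = ("positive", "negative")


@dataclass(frozen=True)
class EdgeMask:
    """A signed subset of edge indices out of ``n_edges`` total."""

    indices: np.ndarray
    sign: str
    n_edges: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if idx.size and (idx[0] < 0 or idx[-1] >= self.n_edges):
            raise ValueError(f"edge indices out of range 0..{self.n_edges - 1}")
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def as_set(self) -> frozenset[int]:
        return frozenset(int(i) for i in self.indices)


class EdgeAssociation(NamedTuple):
    """Per-edge correlation with the score and its two-sided p-value."""

    r: np.ndarray
    p: np.ndarray


@dataclass(frozen=True)
class CPMModel:
    """Selected masks plus the linear network-strength models.

    ``pos_coefficients`` / ``neg_coefficients`` are (intercept, slope) in
    score units and score units per unit summed Fisher-z respectively.
    ``combined_coefficients`` is (intercept, b_pos, b_neg) and only set for
    the ``two_predictor`` rule; the default rule predicts the combined
    score as the sum of the two single-model predictions.
    """

    pos_mask: EdgeMask
    neg_mask: EdgeMask
    pos_coefficients: tuple[float, float]
    neg_coefficients: tuple[float, float]
    combined_rule: str = "sum_of_predictions"
    combined_coefficients: tuple[float, float, float] | None = None
    selection_threshold: float = float("nan")

    def __post_init__(self) -> None:
        if self.combined_rule not in COMBINED_RULES:
            raise ValueError(f"combined_rule must be one of {COMBINED_RULES}")
        if self.pos_mask.n_edges != self.neg_mask.n_edges:
            raise ValueError("pos and neg masks reference different edge counts")
        for coef in (self.pos_coefficients, self.neg_coefficients):
            if not all(np.isfinite(coef)):
                raise ValueError("non-finite model coefficients")


@dataclass(frozen=True)
class FoldResult:
    """One LOOCV fold: masks fit without the held-out subject, plus predictions."""

    held_out_subject: str
    predicted_pos: float
    predicted_neg: float
    predicted_combined: float
    pos_mask: EdgeMask
    neg_mask: EdgeMask


@dataclass(frozen=True)
class LoocvResult:
    folds: tuple[FoldResult, ...]
    predicted: np.ndarray          # combined predictions, subject order
    predicted_pos: np.ndarray
    predicted_neg: np.ndarray
    observed: np.ndarray
    threshold: float
    method: str
    combined_rule: str

    @property
    def fold_pos_masks(self) -> list[EdgeMask]:
        return [f.pos_mask for f in self.folds]

    @property
    def fold_neg_masks(self) -> list[EdgeMask]:
        return [f.neg_mask for f in self.folds]


def _columnwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Pearson r of each column of x against y; constant columns get r = 0."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    ssx = np.einsum("ij,ij->j", xc, xc)
    ssy = float(yc @ yc)
    if ssy == 0.0:
        raise ValueError("score has zero variance")
    denom = np.sqrt(ssx * ssy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / denom
    n_const = int(np.count_nonzero(ssx == 0.0))
    if n_const:
        logger.warning("%d constant edge column(s); r set to 0, p to 1", n_const)
        r = np.where(ssx == 0.0, 0.0, r)
    return np.clip(r, -1.0, 1.0), n_const


def _p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p of a correlation from the t distribution with df degrees."""
    if df < 1:
        raise ValueError(f"nonpositive degrees of freedom ({df}); too few subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, df)
    return np.where(np.abs(r) >= 1.0, 0.0, np.minimum(p, 1.0))


def _residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``values`` on covariates + intercept."""
    design = np.column_stack([np.ones(len(covariates)), covariates])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def edge_behavior_association(
    dataset: CohortDataset,
    method: str = "pearson",
    covariate_names: Sequence[str] | None = None,
) -> EdgeAssociation:
    """Correlate every edge with the score across subjects.

    ``method="pearson"`` is the plain Pearson correlation with two-sided
    p from the t distribution on n - 2 df. ``method="partial_pearson"``
    first residualizes both edges and score on the named covariates (all
    cohort covariates by default) with an intercept, reducing df by the
    covariate count.
    """
    if dataset.n_subjects < 4:
        raise ValueError("edge-behavior association needs at least 4 subjects")
    x = dataset.edge_matrix
    y = dataset.score
    df = dataset.n_subjects - 2
    if method == "partial_pearson":
        z = dataset.covariate_matrix(covariate_names)
        x = _residualize(x, z)
        y = _residualize(y[:, None], z)[:, 0]
        df -= z.shape[1]
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r, _ = _columnwise_pearson(x, y)
    return EdgeAssociation(r=r, p=_p_from_r(r, df))


def select_edges(
    assoc: EdgeAssociation, threshold: float
) -> tuple[EdgeMask, EdgeMask]:
    """Threshold the association: strict p < threshold, split by sign of r.

    Edges with r exactly 0 are never selected; the two masks are disjoint
    by construction.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    r, p = np.asarray(assoc.r), np.asarray(assoc.p)
    sig = p < threshold
    pos = np.flatnonzero(sig & (r > 0.0))
    neg = np.flatnonzero(sig & (r < 0.0))
    E = r.size
    return (
        EdgeMask(indices=pos, sign="positive", n_edges=E),
        EdgeMask(indices=neg, sign="negative", n_edges=E),
    )


def network_strength(edge_values: np.ndarray, mask: EdgeMask) -> np.ndarray | float:
    """Sum of edge values at the mask's indices (0 for an empty mask).

    Accepts one subject's edge vector or a subjects x edges matrix; returns
    a scalar or a per-subject vector accordingly.
    """
    edge_values = np.asarray(edge_values, dtype=float)
    if edge_values.shape[-1] != mask.n_edges:
        raise ValueError(
            f"edge vector length {edge_values.shape[-1]} != mask n_edges {mask.n_edges}"
        )
    if len(mask) == 0:
        out = np.zeros(edge_values.shape[:-1])
    else:
        out = edge_values[..., mask.indices].sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def _ols_line(strength: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of score on strength; degenerate -> (mean, 0)."""
    sc = strength - strength.mean()
    ss = float(sc @ sc)
    if ss == 0.0:
        return float(y.mean()), 0.0
    slope = float(sc @ (y - y.mean())) / ss
    return float(y.mean() - slope * strength.mean()), slope


def fit_cpm(
    train: CohortDataset,
    pos: EdgeMask,
    neg: EdgeMask,
    combined_rule: str = "sum_of_predictions",
    selection_threshold: float = float("nan"),
) -> CPMModel:
    """Fit the positive/negative network-strength models on a training cohort.

    An empty mask yields the degenerate model (intercept = training mean
    score, slope = 0), so small cohorts at strict thresholds still complete.
    """
    if train.n_subjects < 3:
        raise ValueError("fit_cpm needs at least 3 training subjects")
    if len(pos) == 0 or len(neg) == 0:
        logger.warning(
            "empty %s mask(s); degenerate mean-score model used",
            "/".join(s for s, m in (("positive", pos), ("negative", neg)) if len(m) == 0),
        )
    y = train.score
    s_pos = np.asarray(network_strength(train.edge_matrix, pos))
    s_neg = np.asarray(network_strength(train.edge_matrix, neg))
    combined_coef = None
    if combined_rule == "two_predictor":
        design = np.column_stack([np.ones(train.n_subjects), s_pos, s_neg])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        combined_coef = (float(coef[0]), float(coef[1]), float(coef[2]))
    return CPMModel(
        pos_mask=pos,
        neg_mask=neg,
        pos_coefficients=_ols_line(s_pos, y),
        neg_coefficients=_ols_line(s_neg, y),
        combined_rule=combined_rule,
        combined_coefficients=combined_coef,
        selection_threshold=selection_threshold,
    )


def predict_cpm(
    model: CPMModel, edge_values: np.ndarray
) -> tuple[np.ndarray | float, np.ndarray | float, np.ndarray | float]:
    """(pred_pos, pred_neg, pred_combined) for one edge vector or a matrix."""
    s_pos = network_strength(edge_values, model.pos_mask)
    s_neg = network_strength(edge_values, model.neg_mask)
    a_p, b_p = model.pos_coefficients
    a_n, b_n = model.neg_coefficients
    pred_pos = a_p + b_p * np.asarray(s_pos)
    pred_neg = a_n + b_n * np.asarray(s_neg)
    if model.combined_rule == "two_predictor":
        c0, c1, c2 = model.combined_coefficients
        pred_combined = c0 + c1 * np.asarray(s_pos) + c2 * np.asarray(s_neg)
    else:
        pred_combined = pred_pos + pred_neg
    if np.ndim(pred_combined) == 0:
        return float(pred_pos), float(pred_neg), float(pred_combined)
    return pred_pos, pred_neg, pred_combined


class PearsonLoocvEngine:
    """Vectorized leave-one-out folds for plain-Pearson edge selection.

    Precomputes the edge-side sufficient statistics once; ``fold_association``
    and ``run`` then cost a few dense array passes per score vector, which
    makes permutation testing (many shuffled scores over fixed connectomes)
    cheap. The per-fold correlations equal a from-scratch recomputation on
    the n-1 training rows up to floating-point rounding.
    """

    def __init__(self, dataset: CohortDataset, threshold: float, combined_rule: str):
        if dataset.n_subjects < 5:
            raise ValueError("LOOCV needs at least 5 subjects")
        if not (0.0 < threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if combined_rule not in COMBINED_RULES:
            raise ValueError(f"combined_rule must be one of {COMBINED_RULES}")
        self.dataset = dataset
        self.threshold = threshold
        self.combined_rule = combined_rule
        X = dataset.edge_matrix
        self.n, self.E = X.shape
        self.X = X
        sx = X.sum(axis=0)
        sxx = np.einsum("ij,ij->j", X, X)
        # per-fold (row f removed) edge sums / sums of squares
        self.sx_f = sx[None, :] - X
        m = self.n - 1
        self.varx_f = m * (sxx[None, :] - X * X) - self.sx_f**2
        self.df = m - 2
        if self.df < 1:
            raise ValueError("too few subjects for per-fold correlation p-values")
        # p < threshold is equivalent to |r| > r_crit (two-sided t test, df fixed
        # across folds); thresholding on r avoids a folds x edges p-value pass
        t_crit = stats.t.isf(threshold / 2.0, self.df)
        self.r_crit = t_crit / math.sqrt(t_crit * t_crit + self.df)

    def fold_association(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(r, p), each folds x edges, for score vector y."""
        X = self.X
        m = self.n - 1
        sy = float(y.sum())
        syy = float(y @ y)
        sxy = y @ X
        sy_f = sy - y
        vary_f = m * (syy - y * y) - sy_f**2
        cov_f = m * (sxy[None, :] - X * y[:, None]) - self.sx_f * sy_f[:, None]
        denom = self.varx_f * vary_f[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov_f / np.sqrt(denom)
        r = np.where(self.varx_f <= 0.0, 0.0, r)
        if np.any(vary_f <= 0.0):
            bad = int(np.flatnonzero(vary_f <= 0.0)[0])
            raise ValueError(
                f"score constant in training fold holding out subject index {bad}"
            )
        np.clip(r, -1.0, 1.0, out=r)
        return r, _p_from_r(r, self.df)

    def run(self, y: np.ndarray, collect_folds: bool = True) -> LoocvResult:
        X = self.X
        n = self.n
        m = n - 1
        sy = float(y.sum())
        syy = float(y @ y)
        sxy = y @ X
        sy_f = sy - y
        vary_f = m * (syy - y * y) - sy_f**2
        if np.any(vary_f <= 0.0):
            bad = int(np.flatnonzero(vary_f <= 0.0)[0])
            raise ValueError(
                f"score constant in training fold holding out subject index {bad}"
            )
        cov_f = m * (sxy[None, :] - X * y[:, None]) - self.sx_f * sy_f[:, None]
        # cov^2 > r_crit^2 * varx * vary  <=>  |r| > r_crit  <=>  p < threshold
        crit = (self.r_crit * self.r_crit) * self.varx_f * vary_f[:, None]
        sig = cov_f * cov_f > crit
        folds: list[FoldResult] = []
        pred_pos = np.empty(n)
        pred_neg = np.empty(n)
        pred_comb = np.empty(n)
        for f in range(n):
            pos_idx = np.flatnonzero(sig[f] & (cov_f[f] > 0.0))
            neg_idx = np.flatnonzero(sig[f] & (cov_f[f] < 0.0))
            rows = np.concatenate([np.arange(f), np.arange(f + 1, n)])
            y_train = y[rows]
            s_pos_all = X[:, pos_idx].sum(axis=1) if pos_idx.size else np.zeros(n)
            s_neg_all = X[:, neg_idx].sum(axis=1) if neg_idx.size else np.zeros(n)
            a_p, b_p = _ols_line(s_pos_all[rows], y_train)
            a_n, b_n = _ols_line(s_neg_all[rows], y_train)
            pp = a_p + b_p * s_pos_all[f]
            pn = a_n + b_n * s_neg_all[f]
            if self.combined_rule == "two_predictor":
                design = np.column_stack(
                    [np.ones(n - 1), s_pos_all[rows], s_neg_all[rows]]
                )
                coef, *_ = np.linalg.lstsq(design, y_train, rcond=None)
                pc = float(coef[0] + coef[1] * s_pos_all[f] + coef[2] * s_neg_all[f])
            else:
                pc = pp + pn
            pred_pos[f], pred_neg[f], pred_comb[f] = pp, pn, pc
            if collect_folds:
                folds.append(
                    FoldResult(
                        held_out_subject=self.dataset.subject_ids[f],
                        predicted_pos=float(pp),
                        predicted_neg=float(pn),
                        predicted_combined=float(pc),
                        pos_mask=EdgeMask(pos_idx, "positive", self.E),
                        neg_mask=EdgeMask(neg_idx, "negative", self.E),
                    )
                )
        return LoocvResult(
            folds=tuple(folds),
            predicted=pred_comb,
            predicted_pos=pred_pos,
            predicted_neg=pred_neg,
            observed=y.copy(),
            threshold=self.threshold,
            method="pearson",
            combined_rule=self.combined_rule,
        )


def loocv_cpm(
    dataset: CohortDataset,
    threshold: float,
    method: str = "pearson",
    combined_rule: str = "sum_of_predictions",
    covariate_names: Sequence[str] | None = None,
) -> LoocvResult:
    """Leave-one-subject-out cross-validated CPM.

    For each subject: edge selection and model fitting on all other
    subjects, then prediction for the held-out subject. Deterministic; the
    per-fold masks are retained for the transfer and anatomy stages.
    ``covariate_names`` only matters for ``method="partial_pearson"``.
    """
    if dataset.n_subjects < 5:
        raise ValueError("LOOCV needs at least 5 subjects")
    if method == "pearson":
        return PearsonLoocvEngine(dataset, threshold, combined_rule).run(dataset.score)
    n = dataset.n_subjects
    folds: list[FoldResult] = []
    pred_pos = np.empty(n)
    pred_neg = np.empty(n)
    pred_comb = np.empty(n)
    for f in range(n):
        rows = np.concatenate([np.arange(f), np.arange(f + 1, n)])
        train = dataset.subset(rows)
        try:
            assoc = edge_behavior_association(train, method, covariate_names)
            pos, neg = select_edges(assoc, threshold)
            model = fit_cpm(train, pos, neg, combined_rule, threshold)
        except ValueError as exc:
            raise ValueError(
                f"fold holding out subject {dataset.subject_ids[f]!r}: {exc}"
            ) from exc
        pp, pn, pc = predict_cpm(model, dataset.edge_matrix[f])
        pred_pos[f], pred_neg[f], pred_comb[f] = pp, pn, pc
        folds.append(
            FoldResult(
                held_out_subject=dataset.subject_ids[f],
                predicted_pos=pp,
                predicted_neg=pn,
                predicted_combined=pc,
                pos_mask=pos,
                neg_mask=neg,
            )
        )
    return LoocvResult(
        folds=tuple(folds),
        predicted=pred_comb,
        predicted_pos=pred_pos,
        predicted_neg=pred_neg,
        observed=dataset.score.copy(),
        threshold=threshold,
        method=method,
        combined_rule=combined_rule,
    )
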