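"""Evaluation and permutation inference for CPM predictions.

Predicted vs. observed agreement is summarized by a Spearman *partial*
correlation controlling for nuisance covariates (canonically age and
in-scanner motion): all variables are rank-transformed (average ranks for
ties), the ranked prediction and ranked observation are residualized on the
ranked covariates plus an intercept by OLS, and the Pearson correlation of
the residuals is returned. With zero covariates this reduces exactly to the
classical Spearman rho.

Significance comes from a shuffled-label null: scores are randomly permuted
across subjects (covariates stay attached to their subjects' connectomes),
the full cross-validated pipeline — including edge re-selection in every
fold — is re-run per permutation, and the one-sided add-one p-value
p = (1 + #{null >= observed}) / (1 + n_perm) is reported, so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PearsonLoocvEngine, loocv_cpm
from .datamodel import CohortDataset

__all__ = [
    "EvaluationResult",
    "PermutationResult",
    "spearman_partial",
    "evaluate_predictions",
    "permutation_test",
    "evaluate_consistency",
]


@dataclass(frozen=True)
class EvaluationResult:
    rho: float
    covariate_names: tuple[str, ...]
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho) or abs(self.rho) > 1.0 + 1e-12:
            raise ValueError(f"invalid rho {self.rho}")


@dataclass(frozen=True)
class PermutationResult:
    observed_rho: float
    null_rhos: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.null_rhos) != self.n_perm:
            raise ValueError("null_rhos length must equal n_perm")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def _as_cov_array(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    return z if z.shape[1] else None


def spearman_partial(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> float:
    """Spearman correlation of x and y partialling out ranked covariates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = _as_cov_array(covariates)
    n = len(x)
    if len(y) != n or (z is not None and len(z) != n):
        raise ValueError("x, y and covariates must be aligned")
    n_cov = 0 if z is None else z.shape[1]
    if n < n_cov + 3:
        raise ValueError(f"need at least {n_cov + 3} observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        raise ValueError("constant input after ranking; rho undefined")
    if z is not None:
        rz = np.column_stack([stats.rankdata(col) for col in z.T])
        design = np.column_stack([np.ones(n), rz])
        coef, *_ = np.linalg.lstsq(design, np.column_stack([rx, ry]), rcond=None)
        res = np.column_stack([rx, ry]) - design @ coef
        rx, ry = res[:, 0], res[:, 1]
        if float(rx @ rx) == 0.0 or float(ry @ ry) == 0.0:
            raise ValueError("no residual variance after partialling covariates")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float(rxc @ ryc / np.sqrt((rxc @ rxc) * (ryc @ ryc)))


def evaluate_predictions(
    predicted: np.ndarray,
    observed: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: Sequence[str] = (),
) -> EvaluationResult:
    """Wrap :func:`spearman_partial`, recording n and the covariate names."""
    if isinstance(covariates, pd.DataFrame) and not covariate_names:
        covariate_names = tuple(covariates.columns)
    rho = spearman_partial(predicted, observed, covariates)
    return EvaluationResult(rho=rho, covariate_names=tuple(covariate_names), n=len(predicted))


def permutation_test(
    dataset: CohortDataset,
    threshold: float,
    method: str = "pearson",
    combined_rule: str = "sum_of_predictions",
    covariate_names: Sequence[str] = ("age", "motion"),
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Shuffled-score permutation null for the LOOCV predicted-observed rho.

    Each permutation draws a uniformly random permutation of the score
    vector only (covariates are not permuted — they stay with their
    subjects), re-runs the full LOOCV including edge re-selection, and
    re-evaluates. Reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    z = dataset.covariate_matrix(covariate_names) if covariate_names else None
    rng = np.random.default_rng(seed)

    if method == "pearson":
        engine = PearsonLoocvEngine(dataset, threshold, combined_rule)

        def run(y: np.ndarray) -> np.ndarray:
            return engine.run(y, collect_folds=False).predicted

    else:

        def run(y: np.ndarray) -> np.ndarray:
            shuffled = CohortDataset(
                edge_matrix=dataset.edge_matrix,
                score=y,
                covariates=dataset.covariates,
                subject_ids=dataset.subject_ids,
                node_count=dataset.node_count,
            )
            return loocv_cpm(shuffled, threshold, method, combined_rule, covariate_names).predicted

    observed_rho = spearman_partial(run(dataset.score), dataset.score, z)
    null_rhos = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(dataset.score)
        try:
            null_rhos[b] = spearman_partial(run(y_perm), y_perm, z)
        except ValueError as exc:
            raise ValueError(f"permutation {b}: {exc}") from exc
    p_value = (1.0 + float(np.count_nonzero(null_rhos >= observed_rho))) / (1.0 + n_perm)
    return PermutationResult(
        observed_rho=observed_rho,
        null_rhos=null_rhos,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
    )


def evaluate_consistency(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    observed: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> float:
    """Spearman partial correlation between two models' prediction deviations.

    Measures whether two models (e.g. a within-cohort model and an
    externally trained one) err on the same subjects: the deviations
    (pred_a - observed) and (pred_b - observed) are compared.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    observed = np.asarray(observed, dtype=float)
    return spearman_partial(pred_a - observed, pred_b - observed, covariates)
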