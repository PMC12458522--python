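"""Cross-cohort model transfer via consensus edge masks.

In leave-one-out cross-validation each fold corresponds to one held-out
subject, so "edges significant in X% of subjects" is read as edges present
in at least ceil(X% of n_folds) per-fold masks. A consensus model at a
given fraction refits the positive/negative network-strength coefficients
by OLS on the *full* training cohort using the consensus masks, and can
then be applied to any external cohort sharing the parcellation (edge
indexing must agree; node counts are checked). Evaluation is rank-based,
so no calibration of predicted scores to the target's scale is attempted.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CPMModel, EdgeMask, fit_cpm, predict_cpm
from .datamodel import CohortDataset, edge_count
from .inference import EvaluationResult, evaluate_predictions

__all__ = [
    "ConsensusModel",
    "consensus_mask",
    "fit_consensus_model",
    "apply_external_model",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusModel:
    """A portable CPM: consensus masks plus full-cohort coefficients."""

    fraction: float
    pos_mask: EdgeMask
    neg_mask: EdgeMask
    pos_coefficients: tuple[float, float]
    neg_coefficients: tuple[float, float]
    combined_rule: str = "sum_of_predictions"
    combined_coefficients: tuple[float, float, float] | None = None
    source_cohort: str = ""
    node_count: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if self.node_count and edge_count(self.node_count) != self.pos_mask.n_edges:
            raise ValueError("node_count inconsistent with mask edge count")

    def as_cpm_model(self) -> CPMModel:
        return CPMModel(
            pos_mask=self.pos_mask,
            neg_mask=self.neg_mask,
            pos_coefficients=self.pos_coefficients,
            neg_coefficients=self.neg_coefficients,
            combined_rule=self.combined_rule,
            combined_coefficients=self.combined_coefficients,
        )


def _consensus_count(fraction: float, n_folds: int) -> int:
    # guard against float ceil artifacts (0.9 * 10 == 9.000000000000002)
    return max(1, int(math.ceil(fraction * n_folds - 1e-9)))


def consensus_mask(fold_masks: Sequence[EdgeMask], fraction: float) -> EdgeMask:
    """Edges present in at least ceil(fraction * n_folds) of the fold masks.

    fraction -> 0+ gives the union of fold masks (the "low threshold": any
    edge identified in any fold); fraction = 1.0 gives their intersection.
    """
    if not fold_masks:
        raise ValueError("fold_masks is empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    signs = {m.sign for m in fold_masks}
    sizes = {m.n_edges for m in fold_masks}
    if len(signs) != 1:
        raise ValueError(f"mixed mask signs {sorted(signs)}")
    if len(sizes) != 1:
        raise ValueError(f"mixed edge counts {sorted(sizes)}")
    (sign,), (E,) = signs, sizes
    counts = np.zeros(E, dtype=np.int64)
    for m in fold_masks:
        counts[m.indices] += 1
    need = _consensus_count(fraction, len(fold_masks))
    return EdgeMask(indices=np.flatnonzero(counts >= need), sign=sign, n_edges=E)


def fit_consensus_model(
    train: CohortDataset,
    fold_masks_pos: Sequence[EdgeMask],
    fold_masks_neg: Sequence[EdgeMask],
    fraction: float,
    combined_rule: str = "sum_of_predictions",
    source_cohort: str = "train",
) -> ConsensusModel:
    """Build consensus masks at ``fraction`` and refit on the full cohort."""
    pos = consensus_mask(fold_masks_pos, fraction)
    neg = consensus_mask(fold_masks_neg, fraction)
    if len(pos) == 0 or len(neg) == 0:
        logger.warning(
            "empty consensus mask at fraction %.2f (pos=%d, neg=%d edges); "
            "degenerate mean-score model for the empty side",
            fraction,
            len(pos),
            len(neg),
        )
    fitted = fit_cpm(train, pos, neg, combined_rule)
    return ConsensusModel(
        fraction=fraction,
        pos_mask=pos,
        neg_mask=neg,
        pos_coefficients=fitted.pos_coefficients,
        neg_coefficients=fitted.neg_coefficients,
        combined_rule=combined_rule,
        combined_coefficients=fitted.combined_coefficients,
        source_cohort=source_cohort,
        node_count=train.node_count,
    )


def apply_external_model(
    model: ConsensusModel,
    target: CohortDataset,
    covariate_names: Sequence[str] = ("age", "motion"),
) -> tuple[np.ndarray, EvaluationResult]:
    """Predict the target cohort from a trained consensus model and evaluate.

    Evaluation is the Spearman partial correlation of predicted vs.
    observed scores controlling the named covariates.
    """
    if model.node_count and model.node_count != target.node_count:
        raise ValueError(
            f"node_count mismatch: model trained on {model.node_count} nodes, "
            f"target has {target.node_count}"
        )
    if model.pos_mask.n_edges != target.n_edges:
        raise ValueError(
            f"edge-count mismatch: model {model.pos_mask.n_edges}, target {target.n_edges}"
        )
    _, _, predicted = predict_cpm(model.as_cpm_model(), target.edge_matrix)
    z = target.covariate_matrix(covariate_names) if covariate_names else None
    evaluation = evaluate_predictions(
        predicted, target.score, z, covariate_names=tuple(covariate_names or ())
    )
    return np.asarray(predicted), evaluation


def save_model(model: ConsensusModel, path: os.PathLike | str) -> None:
    """Serialize a consensus model as a plain-text JSON bundle."""
    payload = {
        "format": "cpmkit-consensus-model",
        "fraction": model.fraction,
        "node_count": model.node_count,
        "n_edges": model.pos_mask.n_edges,
        "source_cohort": model.source_cohort,
        "combined_rule": model.combined_rule,
        "pos_indices": model.pos_mask.indices.tolist(),
        "neg_indices": model.neg_mask.indices.tolist(),
        "pos_coefficients": list(model.pos_coefficients),
        "neg_coefficients": list(model.neg_coefficients),
        "combined_coefficients": (
            list(model.combined_coefficients) if model.combined_coefficients else None
        ),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path: os.PathLike | str) -> ConsensusModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "cpmkit-consensus-model":
        raise ValueError(f"{path}: not a consensus-model bundle")
    E = int(payload["n_edges"])
    combined = payload.get("combined_coefficients")
    return ConsensusModel(
        fraction=float(payload["fraction"]),
        pos_mask=EdgeMask(np.asarray(payload["pos_indices"], dtype=np.int64), "positive", E),
        neg_mask=EdgeMask(np.asarray(payload["neg_indices"], dtype=np.int64), "negative", E),
        pos_coefficients=tuple(payload["pos_coefficients"]),
        neg_coefficients=tuple(payload["neg_coefficients"]),
        combined_rule=payload["combined_rule"],
        combined_coefficients=tuple(combined) if combined else None,
        source_cohort=payload.get("source_cohort", ""),
        node_count=int(payload["node_count"]),
    )
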