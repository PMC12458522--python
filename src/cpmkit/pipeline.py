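"""End-to-end orchestration: within-cohort runs and cross-cohort transfer.

`run_within_cohort` reproduces the full within-cohort protocol for each
edge-selection threshold: LOOCV, Spearman-partial evaluation against the
configured covariates, and the shuffled-score permutation null. Defaults
mirror the reference configuration: thresholds p < .05/.01/.005, consensus
fractions 25/50/75/90/100%, covariates age + motion, 1000 permutations.

All report artifacts are delimited text plus a JSON manifest (config,
seed, package and library versions), so a run is regenerable byte-for-byte
from (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import EdgeMask, LoocvResult, loocv_cpm
from .datamodel import CohortDataset
from .inference import PermutationResult, evaluate_predictions, permutation_test
from .transfer import ConsensusModel, fit_consensus_model, save_model

__all__ = [
    "RunConfig",
    "ThresholdReport",
    "WithinCohortReport",
    "TransferReport",
    "run_within_cohort",
    "run_transfer",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.005)
    consensus_fractions: tuple[float, ...] = (0.25, 0.50, 0.75, 0.90, 1.00)
    covariate_names: tuple[str, ...] = ("age", "motion")
    n_perm: int = 1000
    seed: int = 0
    combined_rule: str = "sum_of_predictions"
    method: str = "pearson"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f: mapping[f] for f in cls.__dataclass_fields__ if f in mapping}
        for key in ("thresholds", "consensus_fractions", "covariate_names"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    rho: float
    p_value: float
    predicted_mean: float
    predicted_sd: float
    loocv: LoocvResult
    permutation: PermutationResult


@dataclass(frozen=True)
class WithinCohortReport:
    config: RunConfig
    per_threshold: tuple[ThresholdReport, ...]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [t.threshold for t in self.per_threshold],
                "rho": [t.rho for t in self.per_threshold],
                "p_value": [t.p_value for t in self.per_threshold],
                "predicted_mean": [t.predicted_mean for t in self.per_threshold],
                "predicted_sd": [t.predicted_sd for t in self.per_threshold],
                "n_perm": [t.permutation.n_perm for t in self.per_threshold],
            }
        )


@dataclass(frozen=True)
class TransferReport:
    rows: pd.DataFrame = field(repr=False)
    models: tuple[ConsensusModel, ...] = ()


def _manifest(config: RunConfig, dataset: CohortDataset, extra: dict | None = None) -> dict:
    import scipy

    manifest = {
        "cpmkit_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "dataset": {
            "n_subjects": dataset.n_subjects,
            "n_edges": dataset.n_edges,
            "node_count": dataset.node_count,
            "covariates": list(dataset.covariate_names),
        },
        "note": "permutation null shuffles scores only; covariates stay with subjects",
    }
    if extra:
        manifest.update(extra)
    return manifest


def _write_fold_masks(masks: Sequence[EdgeMask], ids: Sequence[str], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, mask in zip(ids, masks):
            fh.write(f"{sid}\t" + " ".join(str(i) for i in mask.indices) + "\n")


def run_within_cohort(
    dataset: CohortDataset,
    config: RunConfig = RunConfig(),
    out_dir: "Path | str | None" = None,
) -> WithinCohortReport:
    """LOOCV + evaluation + permutation test at every configured threshold."""
    reports: list[ThresholdReport] = []
    z = dataset.covariate_matrix(config.covariate_names) if config.covariate_names else None
    for threshold in config.thresholds:
        t0 = time.perf_counter()
        try:
            loocv = loocv_cpm(
                dataset, threshold, config.method, config.combined_rule, config.covariate_names
            )
            evaluation = evaluate_predictions(
                loocv.predicted, loocv.observed, z, config.covariate_names
            )
            perm = permutation_test(
                dataset,
                threshold,
                config.method,
                config.combined_rule,
                config.covariate_names,
                n_perm=config.n_perm,
                seed=config.seed,
            )
        except ValueError as exc:
            raise ValueError(f"within-cohort stage, threshold {threshold}: {exc}") from exc
        logger.info(
            "threshold %.4g: rho=%.3f p=%.4g (%.2fs)",
            threshold,
            evaluation.rho,
            perm.p_value,
            time.perf_counter() - t0,
        )
        reports.append(
            ThresholdReport(
                threshold=threshold,
                rho=evaluation.rho,
                p_value=perm.p_value,
                predicted_mean=float(np.mean(loocv.predicted)),
                predicted_sd=float(np.std(loocv.predicted, ddof=1)),
                loocv=loocv,
                permutation=perm,
            )
        )
    report = WithinCohortReport(config=config, per_threshold=tuple(reports))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.summary_frame().to_csv(out / "summary.tsv", sep="\t", index=False)
        for tr in report.per_threshold:
            tag = f"thr{tr.threshold:g}"
            pd.DataFrame(
                {
                    "subject_id": list(dataset.subject_ids),
                    "observed": tr.loocv.observed,
                    "predicted_pos": tr.loocv.predicted_pos,
                    "predicted_neg": tr.loocv.predicted_neg,
                    "predicted_combined": tr.loocv.predicted,
                }
            ).to_csv(out / f"predictions_{tag}.tsv", sep="\t", index=False)
            _write_fold_masks(
                tr.loocv.fold_pos_masks, dataset.subject_ids, out / f"fold_masks_pos_{tag}.txt"
            )
            _write_fold_masks(
                tr.loocv.fold_neg_masks, dataset.subject_ids, out / f"fold_masks_neg_{tag}.txt"
            )
            np.savetxt(out / f"null_rhos_{tag}.tsv", tr.permutation.null_rhos, fmt="%.17g")
        (out / "manifest.json").write_text(
            json.dumps(_manifest(config, dataset), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    return report


def run_transfer(
    source: CohortDataset,
    source_loocv: LoocvResult,
    target: CohortDataset,
    config: RunConfig = RunConfig(),
    out_dir: "Path | str | None" = None,
    source_name: str = "source",
) -> TransferReport:
    """Consensus models at every configured fraction, applied to the target."""
    from .transfer import apply_external_model

    rows = []
    models = []
    for fraction in config.consensus_fractions:
        model = fit_consensus_model(
            source,
            source_loocv.fold_pos_masks,
            source_loocv.fold_neg_masks,
            fraction,
            config.combined_rule,
            source_cohort=source_name,
        )
        _, evaluation = apply_external_model(model, target, config.covariate_names)
        rows.append(
            {
                "fraction": fraction,
                "n_pos_edges": len(model.pos_mask),
                "n_neg_edges": len(model.neg_mask),
                "rho": evaluation.rho,
            }
        )
        models.append(model)
        logger.info(
            "fraction %.2f: %d pos / %d neg edges, rho=%.3f",
            fraction,
            len(model.pos_mask),
            len(model.neg_mask),
            evaluation.rho,
        )
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "transfer.tsv", sep="\t", index=False)
        for model in models:
            save_model(model, out / f"model_f{model.fraction:g}.json")
        (out / "manifest.json").write_text(
            json.dumps(
                _manifest(config, source, {"target": {"n_subjects": target.n_subjects}}),
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
    return TransferReport(rows=frame, models=tuple(models))
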