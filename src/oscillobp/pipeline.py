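"""End-to-end pipeline: simulate → augment → train → predict → CLs →
normality report → accuracy report.

Every stage logs its inputs and seeds; all outputs are CSV (plus a JSON
model file), and a run is fully reproducible from the config and its root
seed.  Confidence-limit seeds are derived from the root seed
independently of training, so re-running with ``skip_train=True`` against
a saved model reproduces the downstream reports exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import climits, dbn, evaluation, normality
from .bootstrap import diagnostics_table
from .cohort import generate_cohort, split_cohort, subject_order
from .config import RunConfig
from .errors import OscilloBPError
from .io import write_measurements

__all__ = ["run_pipeline", "subject_estimates_from_predictions", "cohort_cls"]

logger = logging.getLogger(__name__)


def subject_estimates_from_predictions(
    predictions: pd.DataFrame,
) -> list[climits.SubjectEstimates]:
    """Group a predictions frame into per-subject estimate vectors."""
    out = []
    for sid, grp in predictions.groupby("subject_id", sort=False):
        grp = grp.sort_values("meas_idx")
        out.append(
            climits.SubjectEstimates(
                subject_id=str(sid),
                sbp_estimates=grp["sbp_est"].to_numpy(),
                dbp_estimates=grp["dbp_est"].to_numpy(),
            )
        )
    return out


def cohort_cls(
    estimates: Sequence[climits.SubjectEstimates],
    N: int,
    alpha: float,
    seed: int,
) -> list[climits.ConfidenceLimits]:
    """Confidence limits for every subject, per-subject derived seeds."""
    out = []
    for si, est in enumerate(estimates):
        child = int(
            np.random.SeedSequence([int(seed), 3, si]).generate_state(1)[0] % (2**31)
        )
        out.append(climits.estimate_cl(est, N=N, alpha=alpha, seed=child))
    return out


def run_pipeline(config: RunConfig, skip_train: bool = False) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of the artifacts.

    Stages: synthetic cohort generation, subject-disjoint split,
    parametric-bootstrap feature augmentation, DBN ensemble training (or
    model reuse with ``skip_train``), test-set prediction, per-subject
    confidence limits, the normality/independence report, and the
    accuracy report.  A stage failure aborts with the stage name; outputs
    written so far are left on disk.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    paths: dict[str, Path] = {}
    stage = "simulate"
    try:
        logger.info("stage %s: seed=%d", stage, config.cohort.seed)
        records = generate_cohort(config.cohort)
        paths["cohort"] = out_dir / "cohort.csv"
        write_measurements(records, paths["cohort"])

        stage = "split"
        train_recs, test_recs = split_cohort(records, config.n_train_subjects)
        logger.info(
            "stage split: %d train / %d test records", len(train_recs), len(test_recs)
        )

        stage = "diagnostics"
        first_subject = [
            r for r in test_recs if r.subject_id == subject_order(test_recs)[0]
        ]
        diag = diagnostics_table(
            first_subject,
            n_inner=config.bootstrap.n_inner,
            N=config.bootstrap.N_features,
            alpha=config.bootstrap.alpha,
            seed=config.seed,
        )
        paths["bootstrap_diagnostics"] = out_dir / "bootstrap_diagnostics.csv"
        diag.to_csv(paths["bootstrap_diagnostics"], index=False)

        stage = "train"
        model_path = out_dir / "model.json"
        if skip_train and model_path.exists():
            logger.info("stage train: skipped, reusing %s", model_path)
            models = dbn.load_model(model_path)
            X_test = np.array([r.features for r in test_recs])
            preds = dbn.ensemble_predict(models, X_test)
            predictions = pd.DataFrame(
                {
                    "subject_id": [r.subject_id for r in test_recs],
                    "meas_idx": [r.meas_idx for r in test_recs],
                    "sbp_est": preds[:, 0],
                    "dbp_est": preds[:, 1],
                    "ref_sbp": [r.ref_sbp for r in test_recs],
                    "ref_dbp": [r.ref_dbp for r in test_recs],
                }
            )
        else:
            train_cfg = dbn.TrainConfig(
                **{**config.train.__dict__, "seed": config.seed}
            )
            n_aug = config.bootstrap.N_features
            inner = 1 if config.bootstrap.mode == "raw" else config.bootstrap.n_inner
            logger.info(
                "stage train: ensemble=%d augment_N=%d inner=%d",
                train_cfg.ensemble_size, n_aug, inner,
            )
            models, predictions = dbn.ensemble_train_predict(
                train_recs, test_recs, train_cfg, augment_N=n_aug
            )
            dbn.save_model(models, model_path)
        paths["model"] = model_path
        paths["predictions"] = out_dir / "predictions.csv"
        predictions.to_csv(paths["predictions"], index=False)

        stage = "confidence_limits"
        ests = subject_estimates_from_predictions(predictions)
        cls_list = cohort_cls(
            ests, N=config.bootstrap.N_cl, alpha=config.bootstrap.alpha,
            seed=config.seed,
        )
        paths["cl_report"] = out_dir / "cl_report.csv"
        climits.cl_report(cls_list).to_csv(paths["cl_report"], index=False)

        stage = "normality"
        report = normality.cohort_normality_report(cls_list)
        paths["normality_report"] = out_dir / "normality_report.csv"
        report.summary.to_csv(paths["normality_report"], index_label="stream")

        stage = "evaluation"
        sbp_summary = evaluation.error_summary(
            predictions["sbp_est"], predictions["ref_sbp"]
        )
        dbp_summary = evaluation.error_summary(
            predictions["dbp_est"], predictions["ref_dbp"]
        )
        tables = evaluation.comparison_report(
            {"DNNBoot": {"sbp": sbp_summary, "dbp": dbp_summary, "cls": cls_list}}
        )
        accuracy = tables["me_sde"].merge(tables["bhs"], on="method")
        paths["accuracy"] = out_dir / "accuracy.csv"
        accuracy.to_csv(paths["accuracy"], index=False)
    except OscilloBPError as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise
    logger.info("pipeline complete; artifacts in %s", out_dir)
    return paths
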