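"""End-to-end orchestration: synthesis -> preprocessing + features ->
SVM-RFE selection -> two-branch model training -> device-grading report.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .evaluate import standards_report
from .features import default_registry
from .model import ResNetBiLSTMRegressor
from .selection import SVMConfig, combine_targets, run_rfe
from .synth import SynthConfig, make_dataset


@dataclass
class PipelineConfig:
    """One config object driving every stage; ``seed`` propagates to all."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    split_frac: float = 0.85
    n_selected: int = 60
    rfe_step: int = 2
    combine_mode: str = "merged"
    max_epochs: int = 150
    patience: int = 10
    batch_size: int = 64
    lr: float = 0.001
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        self.synth.seed = self.seed


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return (and optionally write) a run manifest.

    The manifest records the configuration, per-stage sizes, the retained
    feature names and the full evaluation report for SBP and DBP on the
    held-out test split.
    """
    t0 = time.time()
    registry = default_registry()
    manifest: dict = {"config": _config_dict(cfg), "stages": {}}

    try:
        train, test = make_dataset(cfg.synth, split_frac=cfg.split_frac, registry=registry)
        manifest["stages"]["data"] = {
            "n_train_rois": train.n_rois,
            "n_test_rois": test.n_rois,
            "n_records": cfg.synth.n_records,
        }

        F_tr, S_tr, Y_tr = train.stacked()
        F_te, S_te, Y_te = test.stacked()

        svm_cfg = SVMConfig(seed=cfg.seed)
        res_sbp = run_rfe(
            F_tr, Y_tr[:, 0], target_size=cfg.n_selected, step=cfg.rfe_step,
            cfg=svm_cfg, target="sbp", feature_names=registry.names,
        )
        res_dbp = run_rfe(
            F_tr, Y_tr[:, 1], target_size=cfg.n_selected, step=cfg.rfe_step,
            cfg=svm_cfg, target="dbp", feature_names=registry.names,
        )
        selected = combine_targets(res_sbp, res_dbp, mode=cfg.combine_mode)
        manifest["stages"]["selection"] = {
            "n_selected": len(selected),
            "selected_names": [registry.names[i] for i in selected],
        }

        # NaN-impute with training medians before the network
        med = np.nanmedian(F_tr, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        F_tr = np.where(np.isfinite(F_tr), F_tr, med[None, :])
        F_te = np.where(np.isfinite(F_te), F_te, med[None, :])

        X_tr = np.hstack([F_tr[:, selected], S_tr])
        X_te = np.hstack([F_te[:, selected], S_te])

        est = ResNetBiLSTMRegressor(
            n_features=len(selected),
            seq_len=train.seq_len,
            lr=cfg.lr,
            max_epochs=cfg.max_epochs,
            batch_size=cfg.batch_size,
            patience=cfg.patience,
            random_state=cfg.seed,
        )
        est.fit(X_tr, Y_tr)
        manifest["stages"]["training"] = {
            "n_parameters": est.n_parameters_,
            "best_epoch": est.best_epoch_,
            "epochs_run": len(est.history_["train_loss"]),
        }

        pred = est.predict(X_te)
        reports = {
            "sbp": standards_report(Y_te[:, 0], pred[:, 0]).as_dict(),
            "dbp": standards_report(Y_te[:, 1], pred[:, 1]).as_dict(),
        }
        manifest["evaluation"] = reports
        manifest["status"] = "ok"
    except Exception as err:
        manifest["status"] = "failed"
        manifest["error"] = str(err)
        manifest["failed_stage"] = _last_stage(manifest)
        raise
    finally:
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        if cfg.out_dir is not None:
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d


def _last_stage(manifest: dict) -> str:
    stages = list(manifest.get("stages", {}))
    order = ["data", "selection", "training"]
    for name in order:
        if name not in stages:
            return name
    return "evaluation"
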