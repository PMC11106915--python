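"""End-to-end orchestration: simulate -> preprocess -> pretrain -> finetune
-> calibrate -> evaluate.

Every stage derives its randomness from the single global seed in
``RunConfig``, so re-running a stage with the logged stage seed reproduces
its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import synth
from .calibration import build_baseline, calibrate_predictions, calibrated_frame
from .data import (
    Cohort,
    cohort_to_sequences,
    impute_by_grade_median,
    mix_pretraining,
    read_cohort_csv,
    select_panels,
    split_cohort,
    standardize,
    write_cohort_csv,
)
from .metrics import metrics_report
from .network import ModelConfig
from .training import TrainConfig, finetune, pretrain, predictions_on


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "prcrs_run"
    combo: str = "1234"
    lead: int = 1
    seed: int = 0
    n_source_patients: int = 200
    n_target_patients: int = 60
    source_fraction: float = 0.6
    model: ModelConfig = field(default_factory=ModelConfig)
    pretrain_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=10))
    finetune_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=10))
    source_csv: Optional[str] = None
    target_csv: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lead not in (1, 2, 3):
            raise ValueError("lead must be 1, 2 or 3")


def _stage_seed(global_seed: int, stage: str) -> int:
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([global_seed, tag]).generate_state(1)[0] % (2**31))


def run_end_to_end(cfg: RunConfig, log=print) -> Dict:
    """Run the full workflow; returns a dict of artifact paths and metrics."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate / load ---------------------------------------------------
    try:
        if cfg.source_csv:
            source = read_cohort_csv(cfg.source_csv, origin="source")
        else:
            source = synth.generate_cohort(
                synth.source_cohort_config(cfg.n_source_patients, seed=_stage_seed(cfg.seed, "source")),
                origin="source",
            )
        if cfg.target_csv:
            target = read_cohort_csv(cfg.target_csv, origin="target")
        else:
            target = synth.generate_cohort(
                synth.target_cohort_config(cfg.n_target_patients, seed=_stage_seed(cfg.seed, "target")),
                origin="target",
            )
    except FileNotFoundError as e:
        raise StageError("simulate", str(e))
    write_cohort_csv(source, out / "source_cohort.csv")
    write_cohort_csv(target, out / "target_cohort.csv")
    log(f"simulate: source {source.n_patients} patients, target {target.n_patients} patients")

    # --- preprocess --------------------------------------------------------
    try:
        source = select_panels(impute_by_grade_median(source), cfg.combo)
        target = select_panels(impute_by_grade_median(target), cfg.combo)
        train_c, val_c, test_c = split_cohort(target, seed=_stage_seed(cfg.seed, "split"))
        (train_s, val_s, test_s), scaler = standardize(train_c, val_c, test_c)
        mixed = mix_pretraining(source, train_c, cfg.source_fraction, seed=_stage_seed(cfg.seed, "mix"))
        (mixed_s,), _ = standardize(mixed)
        tr_mixed = cohort_to_sequences(mixed_s, cfg.lead)
        tr = cohort_to_sequences(train_s, cfg.lead)
        va = cohort_to_sequences(val_s, cfg.lead)
        te = cohort_to_sequences(test_s, cfg.lead)
    except Exception as e:
        raise StageError("preprocess", str(e))
    log(f"preprocess: {len(tr_mixed)} mixed, {len(tr)}/{len(va)}/{len(te)} target train/val/test sequences")

    # --- pretrain ----------------------------------------------------------
    model_cfg = dataclasses.replace(
        cfg.model,
        n_features=target.schema.n_features(cfg.combo),
        combo=cfg.combo,
        lead=cfg.lead,
        seed=_stage_seed(cfg.seed, "model"),
    )
    pre_cfg = dataclasses.replace(cfg.pretrain_cfg, seed=_stage_seed(cfg.seed, "pretrain"))
    try:
        pre = pretrain(model_cfg, pre_cfg, tr_mixed, va)
    except Exception as e:
        raise StageError("pretrain", str(e))
    pre.best_model.save(out / "pretrained")
    log(f"pretrain: best epoch {pre.best_epoch}")

    # --- finetune ----------------------------------------------------------
    ft_cfg = dataclasses.replace(cfg.finetune_cfg, seed=_stage_seed(cfg.seed, "finetune"))
    try:
        ft = finetune(pre.best_model, tr, va, ft_cfg)
    except Exception as e:
        raise StageError("finetune", str(e))
    model = ft.best_model
    model.save(out / "finetuned")
    log(f"finetune: best epoch {ft.best_epoch}")

    # --- baseline on validation predictions -------------------------------
    try:
        val_grades: List[int] = []
        val_probs: List[float] = []
        for s in va:
            probs = model.predict_proba(s.matrix)[: len(s.labels)]
            val_probs.extend(probs)
            val_grades.extend(3 if y else 0 for y in s.labels)
        baseline = build_baseline(val_probs, val_grades)
    except Exception as e:
        raise StageError("calibrate", str(e))
    baseline.to_csv(out / "baseline.csv")

    # --- calibrated test predictions + metrics ------------------------------
    try:
        y, p = predictions_on(model, te)
        calibrated = calibrate_predictions(p, baseline)
        pids = [s.patient_id for s in te for _ in range(len(s.labels))]
        days = [d for s in te for d in range(len(s.labels))]
        calibrated_frame(pids, days, calibrated).to_csv(out / "test_predictions.csv", index=False)
        report = metrics_report(y, p)
    except Exception as e:
        raise StageError("evaluate", str(e))
    (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    log(f"evaluate: macro F1 {report.macro_f1:.4f}, AUROC {report.auroc:.4f}")

    return {
        "out_dir": str(out),
        "artifacts": {
            "source_cohort": str(out / "source_cohort.csv"),
            "target_cohort": str(out / "target_cohort.csv"),
            "pretrained": str(out / "pretrained.npz"),
            "finetuned": str(out / "finetuned.npz"),
            "baseline": str(out / "baseline.csv"),
            "test_predictions": str(out / "test_predictions.csv"),
            "metrics": str(out / "metrics.json"),
        },
        "metrics": report.to_dict(),
        "pretrain_best_epoch": pre.best_epoch,
        "finetune_best_epoch": ft.best_epoch,
    }
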