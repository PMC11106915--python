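"""Optimisation, pretrain -> finetune transfer, CV and coordinate-wise tuning.

Training minimises per-day two-class cross-entropy over labelled, unpadded
days with Adam.  Transfer learning pretrains on a mixed source/target set
and then fine-tunes on the target training set with the embedding and
encoder parameter groups frozen (decoder and classification head remain
trainable).  The best epoch is chosen by a validation metric (macro F1 by
default, AUROC selectable).
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import Cohort, LabeledSequence, cohort_to_sequences, impute_by_grade_median, make_folds, standardize
from .metrics import auprc, auroc, macro_prf
from .network import ModelConfig, PrcrsModel, init_model, sequence_loss

DEFAULT_FREEZE: Tuple[str, ...] = ("embedding", "encoder")


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 12
    learning_rate: float = 0.001
    class_weights: Optional[Tuple[float, float]] = None
    selection_metric: str = "macro_f1"  # or "auroc"
    seed: int = 0
    freeze_spec: Tuple[str, ...] = DEFAULT_FREEZE

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.selection_metric not in ("macro_f1", "auroc"):
            raise ValueError("selection_metric must be 'macro_f1' or 'auroc'")


@dataclass
class FitResult:
    best_model: PrcrsModel
    best_epoch: int  # 1-based
    history: List[Dict[str, float]] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8), skipping frozen groups."""

    def __init__(self, model: PrcrsModel, lr: float):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in model.params.items()}
        self.v = {n: np.zeros_like(p.data) for n, p in model.params.items()}

    def zero_grad(self) -> None:
        for p in self.model.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for n, p in self.model.params.items():
            if p.grad is None or self.model.is_frozen(n):
                continue
            g = p.grad
            self.m[n] = self.beta1 * self.m[n] + (1 - self.beta1) * g
            self.v[n] = self.beta2 * self.v[n] + (1 - self.beta2) * g * g
            p.data -= self.lr * (self.m[n] / b1c) / (np.sqrt(self.v[n] / b2c) + self.eps)


# ---------------------------------------------------------------------------
# Batching


def _pad_batch(seqs: Sequence[LabeledSequence]):
    b = len(seqs)
    tmax = max(s.matrix.shape[0] for s in seqs)
    f = seqs[0].matrix.shape[1]
    batch = np.zeros((b, tmax, f))
    labels = np.zeros((b, tmax), dtype=np.int64)
    label_mask = np.zeros((b, tmax))
    pad_mask = np.zeros((b, tmax))
    for i, s in enumerate(seqs):
        t = s.matrix.shape[0]
        batch[i, :t] = s.matrix
        pad_mask[i, :t] = 1.0
        nl = len(s.labels)
        labels[i, :nl] = s.labels
        label_mask[i, :nl] = 1.0
    return batch, labels, label_mask, pad_mask


def _epoch_batches(seqs: List[LabeledSequence], batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(seqs))
    for start in range(0, len(seqs), batch_size):
        idx = order[start : start + batch_size]
        yield [seqs[i] for i in idx]


def predictions_on(model: PrcrsModel, seqs: Sequence[LabeledSequence]):
    """Concatenated (labels, severe probabilities) over labelled days."""
    ys, ps = [], []
    for s in seqs:
        prob = model.predict_proba(s.matrix)[: len(s.labels)]
        ys.append(s.labels)
        ps.append(prob)
    return np.concatenate(ys), np.concatenate(ps)


def evaluate_metric(model: PrcrsModel, seqs: Sequence[LabeledSequence], metric: str) -> float:
    y, p = predictions_on(model, seqs)
    if metric == "auroc":
        if len(np.unique(y)) < 2:
            return 0.5
        return auroc(y, p)
    return macro_prf(y, (p >= 0.5).astype(int))[2]


# ---------------------------------------------------------------------------
# Fitting


def fit(model: PrcrsModel, train_seqs: List[LabeledSequence],
        val_seqs: Optional[List[LabeledSequence]], cfg: TrainConfig) -> FitResult:
    """Train in place; restore and return the best-validation-epoch weights.

    Without a validation set the final epoch is kept.  Deterministic given
    ``cfg.seed`` (all shuffling and dropout randomness derive from it).
    """
    if not train_seqs:
        raise ValueError("empty training set")
    opt = Adam(model, cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    history: List[Dict[str, float]] = []
    best_metric, best_epoch, best_state = -np.inf, 1, model.state_dict()
    for epoch in range(1, cfg.epochs + 1):
        losses = []
        for chunk in _epoch_batches(train_seqs, cfg.batch_size, shuffle_rng):
            batch, labels, label_mask, pad_mask = _pad_batch(chunk)
            opt.zero_grad()
            loss = sequence_loss(model, batch, labels, label_mask, pad_mask,
                                 class_weights=cfg.class_weights,
                                 rng=drop_rng if model.config.dropout > 0 else None)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row: Dict[str, float] = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_seqs:
            metric = evaluate_metric(model, val_seqs, cfg.selection_metric)
            row[f"val_{cfg.selection_metric}"] = metric
            if metric > best_metric:
                best_metric, best_epoch, best_state = metric, epoch, model.state_dict()
        else:
            best_epoch, best_state = epoch, model.state_dict()
        history.append(row)
    model.load_state_dict(best_state)
    return FitResult(best_model=model, best_epoch=best_epoch, history=history)


def pretrain(model_cfg: ModelConfig, train_cfg: TrainConfig,
             mixed_train: List[LabeledSequence],
             mixed_val: Optional[List[LabeledSequence]] = None) -> FitResult:
    """Train from random initialisation on the mixed source/target set."""
    model = init_model(model_cfg)
    return fit(model, mixed_train, mixed_val, train_cfg)


def finetune(pretrained: PrcrsModel, target_train: List[LabeledSequence],
             target_val: Optional[List[LabeledSequence]],
             train_cfg: TrainConfig) -> FitResult:
    """Fine-tune a copy of the pretrained model with frozen groups.

    The groups named in ``train_cfg.freeze_spec`` keep their pretrained
    weights bitwise; the rest (decoder + head by default) are updated.
    """
    model = init_model(pretrained.config)
    model.load_state_dict(pretrained.state_dict())
    model.unfreeze_all()
    model.freeze(train_cfg.freeze_spec)
    result = fit(model, target_train, target_val, train_cfg)
    model.unfreeze_all()
    return result


# ---------------------------------------------------------------------------
# Cross-validation


def cross_validate(cohort: Cohort, model_cfg: ModelConfig, train_cfg: TrainConfig,
                   k: int = 5, lead: int = 1, fold_seed: int = 0) -> pd.DataFrame:
    """Patient-level k-fold CV; returns per-fold metrics plus mean and sd rows."""
    folds = make_folds(cohort, k=k, seed=fold_seed)
    imputed = impute_by_grade_median(cohort)
    rows = []
    for i, holdout in enumerate(folds):
        test_c = imputed.subset_patients(holdout)
        train_pids = [p for f in folds for p in f if f is not folds[i]]
        train_c = imputed.subset_patients(train_pids)
        (train_s, test_s), _ = standardize(train_c, test_c)
        tr = cohort_to_sequences(train_s, lead)
        te = cohort_to_sequences(test_s, lead)
        cfg = dataclasses.replace(model_cfg, seed=model_cfg.seed + i)
        res = fit(init_model(cfg), tr, None, train_cfg)
        y, p = predictions_on(res.best_model, te)
        calls = (p >= 0.5).astype(int)
        mp, mr, mf = macro_prf(y, calls)
        row = {"fold": i, "macro_precision": mp, "macro_recall": mr, "macro_f1": mf}
        row["auroc"] = auroc(y, p) if len(np.unique(y)) == 2 else np.nan
        row["auprc"] = auprc(y, p) if len(np.unique(y)) == 2 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("fold")
    df.loc["mean"] = df.mean()
    df.loc["sd"] = df.iloc[:k].std(ddof=1)
    return df


# ---------------------------------------------------------------------------
# Coordinate-wise hyperparameter tuning


def tune_coordinatewise(
    grid: Dict[str, List],
    base_cfg: Dict,
    evaluate: Callable[[Dict], float],
) -> Tuple[Dict, pd.DataFrame]:
    """One-at-a-time hyperparameter search.

    Iterates the hyperparameters in the declared order of ``grid``; for
    each, evaluates every candidate with the others held fixed, fixes the
    best (ties resolved toward the first candidate), then proceeds to the
    next hyperparameter.  Returns the final config and the full trace.
    """
    cfg = dict(base_cfg)
    trace = []
    for name, candidates in grid.items():
        if not candidates:
            raise ValueError(f"empty candidate list for {name!r}")
        best_score, best_value = -np.inf, None
        for cand in candidates:
            trial = dict(cfg)
            trial[name] = cand
            score = evaluate(trial)
            trace.append({"hyperparameter": name, "candidate": cand, "score": score})
            if score > best_score:
                best_score, best_value = score, cand
        cfg[name] = best_value
    return cfg, pd.DataFrame(trace)
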