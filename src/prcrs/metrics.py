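"""Evaluation metrics and experiment harnesses.

Macro precision/recall/F1 treat the severe and non-severe classes
symmetrically (unweighted mean of the per-class metric; an undefined ratio
counts as 0).  AUROC is the probability that a random severe day outranks
a random non-severe day (ties get half credit); AUPRC uses step-wise
interpolation over descending thresholds.  Both are delegated to
scikit-learn, whose definitions coincide with these.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_fscore_support, roc_auc_score


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricsReport:
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    confusion: Tuple[Tuple[int, int], Tuple[int, int]]  # rows: true 0/1, cols: called 0/1

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["confusion"] = [list(r) for r in self.confusion]
        return d


def _check_binary(labels, calls) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int)
    c = np.asarray(calls, dtype=int)
    if y.shape != c.shape:
        raise ValueError("labels and calls must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return y, c


def macro_prf(labels: Sequence[int], calls: Sequence[int]) -> Tuple[float, float, float]:
    """Unweighted two-class mean of precision, recall and F1.

    Macro F1 is the mean of the per-class F1 scores, not the F1 of the
    macro precision/recall pair.
    """
    y, c = _check_binary(labels, calls)
    p, r, f, _ = precision_recall_fscore_support(
        y, c, labels=[0, 1], average="macro", zero_division=0
    )
    return float(p), float(r), float(f)


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney with 0.5 tie credit)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve, step interpolation."""
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def sensitivity_specificity(labels: Sequence[int], calls: Sequence[int]) -> Tuple[float, float]:
    """TP/(TP+FN) and TN/(TN+FP); an empty denominator yields 0."""
    y, c = _check_binary(labels, calls)
    tp = int(((y == 1) & (c == 1)).sum())
    fn = int(((y == 1) & (c == 0)).sum())
    tn = int(((y == 0) & (c == 0)).sum())
    fp = int(((y == 0) & (c == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return sens, spec


def confusion_matrix_2x2(labels, calls) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    y, c = _check_binary(labels, calls)
    return (
        (int(((y == 0) & (c == 0)).sum()), int(((y == 0) & (c == 1)).sum())),
        (int(((y == 1) & (c == 0)).sum()), int(((y == 1) & (c == 1)).sum())),
    )


def metrics_report(labels, scores, threshold: float = 0.5) -> MetricsReport:
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    calls = (s >= threshold).astype(int)
    mp, mr, mf = macro_prf(y, calls)
    sens, spec = sensitivity_specificity(y, calls)
    both = len(np.unique(y)) == 2
    return MetricsReport(
        macro_precision=mp,
        macro_recall=mr,
        macro_f1=mf,
        auroc=auroc(y, s) if both else float("nan"),
        auprc=auprc(y, s) if y.sum() else float("nan"),
        sensitivity=sens,
        specificity=spec,
        confusion=confusion_matrix_2x2(y, calls),
    )


def compare_auroc_ttest(fold_aurocs_a: Sequence[float], fold_aurocs_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test on fold-wise AUROC differences.

    Zero-variance differences make the statistic undefined; by convention a
    zero mean yields (0, 1) and a nonzero mean (inf with the sign of the
    mean, 0), each with a warning.
    """
    a = np.asarray(fold_aurocs_a, dtype=float)
    b = np.asarray(fold_aurocs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fold AUROC vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 folds")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance AUROC differences; t-test degenerate", RuntimeWarning)
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Experiment harnesses (imports deferred to avoid cycles)


def ablation_run(cohort, panel_to_drop: int, model_cfg, train_cfg,
                 lead: int = 1, split_seed: int = 0) -> MetricsReport:
    """Retrain without one panel's factors and report test-set metrics."""
    from .data import META_COLUMNS, Cohort, cohort_to_sequences, impute_by_grade_median, split_cohort, standardize
    from .network import init_model
    from .training import fit, predictions_on

    if panel_to_drop not in (1, 2, 3, 4):
        raise ValueError("panel_to_drop must be 1..4")
    keep = [f for pid in (1, 2, 3, 4) if pid != panel_to_drop for f in cohort.schema.panels[pid]]
    reduced = Cohort(cohort.frame[list(META_COLUMNS) + keep].copy(), origin=cohort.origin, schema=cohort.schema)
    train_c, val_c, test_c = split_cohort(impute_by_grade_median(reduced), seed=split_seed)
    (train_s, val_s, test_s), _ = standardize(train_c, val_c, test_c)
    tr = cohort_to_sequences(train_s, lead)
    va = cohort_to_sequences(val_s, lead)
    te = cohort_to_sequences(test_s, lead)
    cfg = dataclasses.replace(model_cfg, n_features=len(keep))
    res = fit(init_model(cfg), tr, va, train_cfg)
    y, p = predictions_on(res.best_model, te)
    return metrics_report(y, p)


def trajectory_report(model, baseline, sequence, grades: Sequence[int]) -> pd.DataFrame:
    """Per-day raw and calibrated severe-CRS probability for one patient.

    Columns: day, raw ("Probability 1"), calibrated ("Probability 2") and
    the observed severe flag — the per-patient verification view.
    """
    from .calibration import calibrate_predictions
    from .data import binarize_grade

    raw = model.predict_proba(sequence)
    calibrated = calibrate_predictions(raw, baseline)
    return pd.DataFrame(
        {
            "day": np.arange(len(raw)),
            "raw_probability": raw,
            "calibrated_probability": [c.calibrated_probability for c in calibrated],
            "severe": [binarize_grade(g) for g in grades],
        }
    )
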