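"""Empirical probability calibration by rank matching against a baseline.

A raw network probability depends on the model's parameters and is only a
relative ranking signal, not the clinical chance of severe CRS.  The
calibration procedure converts it into a local empirical severe-CRS
prevalence: held-out predictions are sorted by descending probability and
paired with their true severe flags (the *baseline*); a new probability is
matched to the nearest baseline entry, a window of entries around the match
is selected, and the calibrated probability is the fraction of severe cases
inside the window.

The per-side window half-width adapts to the probability region: severe
cases are rare, so high probabilities are sparsely populated (small window,
10), mid probabilities denser (15), low probabilities densest (20).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import binarize_grade


@dataclass(frozen=True)
class CalibrationBaseline:
    """(probability, severe flag) pairs sorted by probability, descending.

    Positions are numbered from 1 at the highest probability.
    """

    probabilities: Tuple[float, ...]
    severe: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.probabilities) == 0:
            raise ValueError("baseline must have at least one entry")
        if len(self.probabilities) != len(self.severe):
            raise ValueError("probabilities and severe flags must align")
        p = np.asarray(self.probabilities)
        if (np.diff(p) > 1e-12).any():
            raise ValueError("baseline probabilities must be non-increasing")

    def __len__(self) -> int:
        return len(self.probabilities)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.severe))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self) + 1),
                "probability": self.probabilities,
                "severe": self.severe,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationBaseline":
        df = pd.read_csv(path).sort_values("position")
        return cls(tuple(df["probability"]), tuple(int(s) for s in df["severe"]))


@dataclass(frozen=True)
class CalibratedPrediction:
    raw_probability: float  # "Probability 1"
    calibrated_probability: float  # "Probability 2"
    matched_position: int  # 1-based
    window_used: Tuple[int, int]  # entries actually taken (above, below)


def build_baseline(probabilities: Sequence[float], grades: Sequence[int]) -> CalibrationBaseline:
    """Sort held-out (probability, grade) pairs into a calibration baseline.

    Stable descending sort by probability; the severe flag is grade >= 3.
    """
    probs = np.asarray(probabilities, dtype=float)
    grades = list(grades)
    if len(probs) != len(grades):
        raise ValueError("probabilities and grades must have equal length")
    if len(probs) == 0:
        raise ValueError("cannot build a baseline from empty inputs")
    order = np.argsort(-probs, kind="stable")
    return CalibrationBaseline(
        probabilities=tuple(float(probs[i]) for i in order),
        severe=tuple(binarize_grade(grades[i]) for i in order),
    )


def window_halfwidth(p: float) -> int:
    """Adaptive per-side window size: 10 above 0.8, 15 in [0.3, 0.8], 20 below 0.3."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if p > 0.8:
        return 10
    if p < 0.3:
        return 20
    return 15


def nearest_position(baseline: CalibrationBaseline, p: float) -> int:
    """1-based baseline position whose probability is closest to ``p``.

    Equidistant ties resolve to the smaller (higher-probability) position.
    """
    probs = np.asarray(baseline.probabilities)
    return int(np.argmin(np.abs(probs - p))) + 1


def empirical_probability(baseline: CalibrationBaseline, p: float) -> CalibratedPrediction:
    """Severe-case fraction in the window around the rank-matched entry.

    The matched entry is included; up to ``window_halfwidth(p)`` entries are
    taken on each side, truncated at the list ends (near the head, all
    available entries above are used).
    """
    m = nearest_position(baseline, p)  # 1-based
    k = window_halfwidth(p)
    lo = max(1, m - k)
    hi = min(len(baseline), m + k)
    flags = baseline.severe[lo - 1 : hi]
    return CalibratedPrediction(
        raw_probability=float(p),
        calibrated_probability=float(sum(flags) / len(flags)),
        matched_position=m,
        window_used=(m - lo, hi - m),
    )


def calibrate_predictions(
    raw_probabilities: Sequence[float], baseline: CalibrationBaseline
) -> List[CalibratedPrediction]:
    """Element-wise empirical calibration of raw model probabilities."""
    return [empirical_probability(baseline, float(p)) for p in raw_probabilities]


def calibrated_frame(
    patient_ids: Sequence[str], days: Sequence[int],
    predictions: Sequence[CalibratedPrediction], threshold: float = 0.5
) -> pd.DataFrame:
    """Tabular view of calibrated predictions (CSV-ready)."""
    return pd.DataFrame(
        {
            "patient_id": list(patient_ids),
            "day": list(days),
            "raw_probability": [c.raw_probability for c in predictions],
            "calibrated_probability": [c.calibrated_probability for c in predictions],
            "call": [int(c.raw_probability >= threshold) for c in predictions],
        }
    )
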