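"""Cohort containers, CSV I/O and preprocessing.

A cohort is a longitudinal table with one row per patient-day: patient id,
day index (0-based, days since CAR-T infusion), CRS grade (0-4) and the
clinical factor columns of the schema.  Missing laboratory values are
permitted and are represented as NaN; the canonical imputation replaces a
missing value with the median of that factor over all patient-days sharing
the same CRS grade (cohort-wide median as fallback).

Severe CRS is grade >= 3; the per-day binary label for a *lead* of ``a``
days is the severity indicator of the grade ``a`` days later, so a sequence
of ``T`` days yields ``T - a`` labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, FactorSchema, validate_combo

META_COLUMNS = ("patient_id", "day", "grade")


class SchemaError(ValueError):
    """A cohort file or frame does not match the factor schema."""


class CohortFormatError(ValueError):
    """Structural problem in a cohort table (duplicates, ordering)."""


@dataclass(frozen=True)
class PatientDayRecord:
    patient_id: str
    day: int
    grade: Optional[int]
    values: Dict[str, float]


@dataclass
class Cohort:
    """Longitudinal clinical observations, one row per patient-day.

    ``frame`` columns: patient_id, day, grade, then factor columns in
    schema order.  Within each patient, days are strictly increasing.
    """

    frame: pd.DataFrame
    origin: str = "target"
    schema: FactorSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        df = self.frame
        for col in META_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        factor_cols = [c for c in df.columns if c not in META_COLUMNS]
        known = set(self.schema.all_factors())
        unknown = [c for c in factor_cols if c not in known]
        if unknown:
            raise SchemaError(f"unknown factor column(s): {unknown}")
        if df.duplicated(subset=["patient_id", "day"]).any():
            raise CohortFormatError("duplicate (patient_id, day) rows")
        self.frame = df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)

    @property
    def factor_columns(self) -> List[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def patient_ids(self) -> List[str]:
        return list(dict.fromkeys(self.frame["patient_id"]))

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def n_patient_days(self) -> int:
        return len(self.frame)

    def iter_patients(self) -> Iterator[Tuple[str, pd.DataFrame]]:
        for pid, g in self.frame.groupby("patient_id", sort=False):
            yield pid, g

    def records(self) -> List[PatientDayRecord]:
        cols = self.factor_columns
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            grade = d["grade"]
            out.append(
                PatientDayRecord(
                    patient_id=str(d["patient_id"]),
                    day=int(d["day"]),
                    grade=None if pd.isna(grade) else int(grade),
                    values={c: d[c] for c in cols},
                )
            )
        return out

    def subset_patients(self, patient_ids: Sequence[str]) -> "Cohort":
        keep = self.frame[self.frame["patient_id"].isin(set(patient_ids))].copy()
        return Cohort(keep, origin=self.origin, schema=self.schema)

    def equals(self, other: "Cohort", atol: float = 0.0, rtol: float = 1e-5) -> bool:
        # rtol default covers round-tripping through 6-significant-digit CSV
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if not (a["patient_id"].astype(str).values == b["patient_id"].astype(str).values).all():
            return False
        for col in a.columns:
            if col == "patient_id":
                continue
            x = a[col].to_numpy(dtype=float)
            y = b[col].to_numpy(dtype=float)
            both_nan = np.isnan(x) & np.isnan(y)
            close = np.isclose(x, y, atol=atol, rtol=rtol)
            if not (both_nan | close).all():
                return False
        return True


# ---------------------------------------------------------------------------
# CSV I/O


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as CSV (UTF-8, header, empty cell = missing)."""
    df = cohort.frame.copy()
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_cohort_csv(path, origin: str = "target", schema: Optional[FactorSchema] = None) -> Cohort:
    """Read a cohort CSV; empty cells become missing values (NaN)."""
    schema = schema or DEFAULT_SCHEMA
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in df.columns:
        if col not in ("patient_id",):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "day" in df.columns:
        df["day"] = df["day"].astype(int)
    return Cohort(df, origin=origin, schema=schema)


# ---------------------------------------------------------------------------
# Labels


def binarize_grade(grade: int) -> int:
    """Severity indicator: 1 iff CRS grade >= 3."""
    g = int(grade)
    if not 0 <= g <= 4:
        raise ValueError(f"grade must be in 0..4, got {grade}")
    return 1 if g >= 3 else 0


def shift_labels(grades: Sequence[int], lead: int) -> List[int]:
    """Per-day severe labels predicted ``lead`` days ahead.

    Label at day ``t`` is the severity indicator of the grade at ``t+lead``;
    the last ``lead`` days have no label and are dropped.
    """
    if lead < 0:
        raise ValueError("lead must be non-negative")
    grades = list(grades)
    return [binarize_grade(grades[t + lead]) for t in range(max(0, len(grades) - lead))]


# ---------------------------------------------------------------------------
# Imputation


class ImputationError(ValueError):
    pass


def impute_by_grade_median(cohort: Cohort, train_mask: Optional[np.ndarray] = None) -> Cohort:
    """Fill missing factor values with per-CRS-grade medians.

    Each missing value is replaced by the median of that factor over all
    patient-days sharing the same grade; when a grade group has no observed
    value for the factor, the cohort-wide median is used instead.

    ``train_mask`` (optional boolean row mask) restricts the rows used to
    compute the medians — a strict mode avoiding information flow from
    held-out rows; the default uses the whole cohort.
    """
    df = cohort.frame.copy()
    if df["grade"].isna().any():
        raise ImputationError("every record needs a grade before imputation")
    stats = df if train_mask is None else df.loc[np.asarray(train_mask, dtype=bool)]
    for col in cohort.factor_columns:
        if stats[col].notna().sum() == 0:
            raise ImputationError(f"factor {col!r} has no observed value")
        global_med = stats[col].median()
        grade_med = stats.groupby("grade")[col].median()
        fill = df["grade"].map(grade_med).fillna(global_med)
        df[col] = df[col].fillna(fill)
    return Cohort(df, origin=cohort.origin, schema=cohort.schema)


# ---------------------------------------------------------------------------
# Panel selection


def select_panels(cohort: Cohort, combo: str) -> Cohort:
    """Restrict a cohort to the factor columns of a panel combination."""
    combo = validate_combo(combo)
    wanted = cohort.schema.factors_for_combo(combo)
    present = [c for c in wanted if c in cohort.frame.columns]
    if len(present) != len(wanted):
        missing = sorted(set(wanted) - set(present))
        raise SchemaError(f"cohort lacks factor column(s) for combo {combo}: {missing}")
    cols = list(META_COLUMNS) + wanted
    return Cohort(cohort.frame[cols].copy(), origin=cohort.origin, schema=cohort.schema)


# ---------------------------------------------------------------------------
# Splitting


def _apportion(n: int, ratios: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment of n items by ratios."""
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    base = [int(np.floor(q)) for q in quotas]
    rem = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def split_cohort(
    cohort: Cohort, ratios: Sequence[float] = (6, 2, 2), seed: int = 0
) -> Tuple[Cohort, ...]:
    """Patient-level split into train/validation/test by largest remainder."""
    pids = cohort.patient_ids
    n_parts = sum(1 for r in ratios if r > 0)
    if len(pids) < n_parts:
        raise ValueError(f"need at least {n_parts} patients, have {len(pids)}")
    sizes = _apportion(len(pids), ratios)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(pids)))
    parts = []
    start = 0
    for sz in sizes:
        chosen = [pids[i] for i in order[start : start + sz]]
        parts.append(cohort.subset_patients(chosen))
        start += sz
    return tuple(parts)


def make_folds(cohort: Cohort, k: int = 5, seed: int = 0) -> List[List[str]]:
    """Patient-level cross-validation folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pids = sorted(cohort.patient_ids)
    if len(pids) < k:
        raise ValueError(f"need at least {k} patients, have {len(pids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    folds: List[List[str]] = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        folds[i % k].append(pids[idx])
    return folds


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class Standardizer:
    """Per-factor z-scoring with statistics frozen on the training set."""

    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, cohort: Cohort, sd_floor: float = 1e-8) -> "Standardizer":
        cols = cohort.factor_columns
        mean = cohort.frame[cols].mean()
        std = cohort.frame[cols].std(ddof=0).clip(lower=sd_floor)
        return cls(mean=mean, std=std)

    def transform(self, cohort: Cohort) -> Cohort:
        df = cohort.frame.copy()
        cols = [c for c in cohort.factor_columns]
        df[cols] = (df[cols] - self.mean[cols]) / self.std[cols]
        return Cohort(df, origin=cohort.origin, schema=cohort.schema)


def standardize(train: Cohort, *others: Cohort) -> Tuple[Tuple[Cohort, ...], Standardizer]:
    """Z-score train columns to mean 0 / sd 1; apply train statistics to others."""
    scaler = Standardizer.fit(train)
    out = (scaler.transform(train),) + tuple(scaler.transform(c) for c in others)
    return out, scaler


# ---------------------------------------------------------------------------
# Source/target mixing


def mix_pretraining(
    source: Cohort, target_train: Cohort, source_fraction: float = 0.6, seed: int = 0
) -> Cohort:
    """Compose the pretraining set from source and target patient-days.

    Patients are sampled (without replacement, whole patients) from each
    cohort until the emitted patient-day share of the source cohort is as
    close as possible to ``source_fraction``, favouring use of all target
    data when the source cohort is the larger one.
    """
    if not 0.0 <= source_fraction <= 1.0:
        raise ValueError("source_fraction must be in [0, 1]")
    if source_fraction == 0.0:
        return Cohort(target_train.frame.copy(), origin="mixed", schema=target_train.schema)
    if source_fraction == 1.0:
        return Cohort(source.frame.copy(), origin="mixed", schema=source.schema)
    if source.n_patient_days == 0 or target_train.n_patient_days == 0:
        raise ValueError("both cohorts must be non-empty for a proper mixture")
    rng = np.random.default_rng(seed)
    n_t = target_train.n_patient_days
    # all target days + enough source days for the requested share
    want_source = source_fraction / (1.0 - source_fraction) * n_t
    src_pids = list(source.patient_ids)
    rng.shuffle(src_pids)
    sizes = source.frame.groupby("patient_id", sort=False).size()
    chosen, acc = [], 0
    for pid in src_pids:
        if acc >= want_source:
            break
        chosen.append(pid)
        acc += int(sizes[pid])
    src_part = source.subset_patients(chosen).frame
    mixed = pd.concat([src_part, target_train.frame], ignore_index=True)
    mixed["patient_id"] = mixed["patient_id"].astype(str)
    return Cohort(mixed, origin="mixed", schema=target_train.schema)


# ---------------------------------------------------------------------------
# Model-ready sequences


@dataclass
class LabeledSequence:
    """One patient's standardized factor matrix with lead-shifted labels."""

    patient_id: str
    matrix: np.ndarray  # (T, F) float
    labels: np.ndarray  # (T - lead,) int
    lead: int

    def __post_init__(self) -> None:
        if len(self.labels) != max(0, self.matrix.shape[0] - self.lead):
            raise ValueError("label length must be T - lead")


def cohort_to_sequences(cohort: Cohort, lead: int = 0) -> List[LabeledSequence]:
    """Turn an imputed, standardized cohort into per-patient sequences.

    Patients whose sequence is not longer than the lead contribute no
    labelled day and are dropped.
    """
    cols = cohort.factor_columns
    out = []
    for pid, g in cohort.iter_patients():
        mat = g[cols].to_numpy(dtype=np.float64)
        if np.isnan(mat).any():
            raise ValueError("sequences require an imputed cohort (no NaN)")
        labels = np.asarray(shift_labels(g["grade"].astype(int).tolist(), lead), dtype=np.int64)
        if len(labels) == 0:
            continue
        out.append(LabeledSequence(patient_id=str(pid), matrix=mat[: len(labels) + lead], labels=labels, lead=lead))
    return out
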