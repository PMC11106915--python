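import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prcrs.data import (
    Cohort,
    CohortFormatError,
    ImputationError,
    SchemaError,
    binarize_grade,
    cohort_to_sequences,
    impute_by_grade_median,
    make_folds,
    mix_pretraining,
    read_cohort_csv,
    select_panels,
    shift_labels,
    split_cohort,
    standardize,
    write_cohort_csv,
    _apportion,
)
from prcrs.schema import DEFAULT_SCHEMA
from tests.conftest import make_cohort_frame


# -- CSV I/O ----------------------------------------------------------------

def test_csv_round_trip(sparse_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    write_cohort_csv(sparse_cohort, path)
    back = read_cohort_csv(path)
    assert sparse_cohort.equals(back, atol=1e-9)


def test_empty_cell_parsed_as_missing(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text("patient_id,day,grade,il_6\np1,0,2,\np1,1,3,4.5\n")
    c = read_cohort_csv(path)
    assert np.isnan(c.frame["il_6"].iloc[0])
    assert c.frame["il_6"].iloc[1] == 4.5


def test_unknown_factor_column_rejected(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text("patient_id,day,grade,unknown_factor\np1,0,2,1.0\n")
    with pytest.raises(SchemaError):
        read_cohort_csv(path)


def test_duplicate_patient_day_rejected():
    frame = make_cohort_frame([("p1", 0, 1, {}), ("p1", 0, 2, {})])
    with pytest.raises(CohortFormatError):
        Cohort(frame)


# -- labels ------------------------------------------------------------------

@pytest.mark.parametrize("grade,expected", [(0, 0), (1, 0), (2, 0), (3, 1), (4, 1)])
def test_binarize_grade(grade, expected):
    assert binarize_grade(grade) == expected


def test_binarize_out_of_range():
    with pytest.raises(ValueError):
        binarize_grade(5)


@pytest.mark.parametrize(
    "grades,lead,expected",
    [
        ([0, 0, 3], 1, [0, 1]),
        ([0, 1, 3, 4], 0, [0, 0, 1, 1]),
        ([0, 2], 3, []),
        ([2, 3, 0, 4], 2, [0, 1]),
    ],
)
def test_shift_labels(grades, lead, expected):
    assert shift_labels(grades, lead) == expected


@given(st.lists(st.integers(0, 4), max_size=12), st.integers(0, 5))
@settings(max_examples=100, deadline=None)
def test_shift_labels_length_identity(grades, lead):
    assert len(shift_labels(grades, lead)) == max(0, len(grades) - lead)


def test_negative_lead_rejected():
    with pytest.raises(ValueError):
        shift_labels([0, 1], -1)


# -- imputation --------------------------------------------------------------

def test_impute_grade_median_basic():
    rows = [
        ("p1", 0, 2, {"il_6": 1.0}),
        ("p2", 0, 2, {"il_6": 2.0}),
        ("p3", 0, 2, {"il_6": 3.0}),
        ("p4", 0, 2, {}),  # missing il_6 at grade 2
    ]
    frame = make_cohort_frame(rows)
    other = [c for c in frame.columns if c not in ("patient_id", "day", "grade", "il_6")]
    frame[other] = 0.0
    out = impute_by_grade_median(Cohort(frame))
    assert out.frame["il_6"].iloc[3] == 2.0


def test_impute_global_fallback():
    rows = [
        ("p1", 0, 0, {"il_6": 4.0}),
        ("p2", 0, 0, {"il_6": 6.0}),
        ("p3", 0, 3, {}),  # grade 3 never observed il_6
    ]
    frame = make_cohort_frame(rows)
    other = [c for c in frame.columns if c not in ("patient_id", "day", "grade", "il_6")]
    frame[other] = 0.0
    out = impute_by_grade_median(Cohort(frame))
    assert out.frame.loc[out.frame["patient_id"] == "p3", "il_6"].iloc[0] == 5.0


def test_impute_identity_when_dense(small_cohort):
    out = impute_by_grade_median(small_cohort)
    assert small_cohort.equals(out)


def test_impute_idempotent_and_matches_oracle(sparse_cohort):
    once = impute_by_grade_median(sparse_cohort)
    twice = impute_by_grade_median(once)
    assert once.equals(twice)
    assert not once.frame[once.factor_columns].isna().any().any()
    # brute-force per-grade median oracle on a sample of filled cells
    df = sparse_cohort.frame
    rng = np.random.default_rng(0)
    missing = np.argwhere(df[sparse_cohort.factor_columns].isna().to_numpy())
    for ri, ci in missing[rng.choice(len(missing), 50, replace=False)]:
        col = sparse_cohort.factor_columns[ci]
        grade = df["grade"].iloc[ri]
        group = df.loc[df["grade"] == grade, col].dropna()
        expected = group.median() if len(group) else df[col].median()
        assert once.frame[col].iloc[ri] == pytest.approx(expected)


def test_impute_all_missing_factor_errors():
    frame = make_cohort_frame([("p1", 0, 0, {"il_6": 1.0}), ("p2", 0, 1, {"il_6": 2.0})])
    with pytest.raises(ImputationError):
        impute_by_grade_median(Cohort(frame))


# -- panel selection ---------------------------------------------------------

@pytest.mark.parametrize("combo,n", [("1234", 42), ("2", 10), ("23", 26)])
def test_select_panels_column_counts(small_cohort, combo, n):
    out = select_panels(small_cohort, combo)
    assert len(out.factor_columns) == n


def test_select_panels_idempotent(small_cohort):
    once = select_panels(small_cohort, "23")
    twice = select_panels(once, "23")
    assert once.equals(twice)


def test_select_panels_preserves_order(small_cohort):
    out = select_panels(small_cohort, "23")
    expected = list(DEFAULT_SCHEMA.panels[2]) + list(DEFAULT_SCHEMA.panels[3])
    assert out.factor_columns == expected


def test_select_panels_bad_combo(small_cohort):
    with pytest.raises(ValueError):
        select_panels(small_cohort, "14")


# -- splitting ---------------------------------------------------------------

def test_split_sizes_exact_ratio(small_cohort):
    tr, va, te = split_cohort(small_cohort, seed=1)
    assert (tr.n_patients, va.n_patients, te.n_patients) == (12, 4, 4)


def test_split_202_patients_largest_remainder():
    # quotas 121.2/40.4/40.4: remainders favour the two smaller parts
    assert _apportion(202, (0.6, 0.2, 0.2)) == [121, 41, 40]


@given(st.integers(3, 500))
@settings(max_examples=200, deadline=None)
def test_apportion_sums_and_matches_oracle(n):
    sizes = _apportion(n, (6, 2, 2))
    assert sum(sizes) == n
    # largest-remainder oracle
    quotas = [n * r / 10 for r in (6, 2, 2)]
    base = [int(q) for q in quotas]
    rem = sorted(range(3), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in rem[: n - sum(base)]:
        base[i] += 1
    assert sizes == base


def test_split_disjoint_union_and_deterministic(small_cohort):
    tr, va, te = split_cohort(small_cohort, seed=3)
    tr2, va2, te2 = split_cohort(small_cohort, seed=3)
    assert tr.patient_ids == tr2.patient_ids and te.patient_ids == te2.patient_ids
    all_pids = set(tr.patient_ids) | set(va.patient_ids) | set(te.patient_ids)
    assert all_pids == set(small_cohort.patient_ids)
    assert not (set(tr.patient_ids) & set(va.patient_ids))
    assert not (set(tr.patient_ids) & set(te.patient_ids))
    assert not (set(va.patient_ids) & set(te.patient_ids))


def test_split_too_few_patients():
    frame = make_cohort_frame([("p1", 0, 0, {"il_6": 1.0}), ("p2", 0, 0, {"il_6": 1.0})])
    with pytest.raises(ValueError):
        split_cohort(Cohort(frame))


def test_folds_partition_and_balance(small_cohort):
    folds = make_folds(small_cohort, k=5, seed=2)
    sizes = sorted(len(f) for f in folds)
    assert sizes == [4, 4, 4, 4, 4]
    flat = [p for f in folds for p in f]
    assert sorted(flat) == sorted(small_cohort.patient_ids)


def test_folds_202_patients_sizes():
    rows = [(f"p{i:03d}", 0, 0, {"il_6": 1.0}) for i in range(202)]
    c = Cohort(make_cohort_frame(rows))
    sizes = sorted((len(f) for f in make_folds(c, k=5, seed=0)), reverse=True)
    assert sizes == [41, 41, 40, 40, 40]


def test_folds_k_too_small(small_cohort):
    with pytest.raises(ValueError):
        make_folds(small_cohort, k=1)


# -- standardization ---------------------------------------------------------

def test_standardize_closed_form():
    rows = [(f"p{i}", 0, 0, {"il_6": float(v)}) for i, v in enumerate([1, 2, 3])]
    frame = make_cohort_frame(rows)
    other = [c for c in frame.columns if c not in ("patient_id", "day", "grade", "il_6")]
    frame[other] = 1.0
    (out,), scaler = standardize(Cohort(frame))
    np.testing.assert_allclose(
        sorted(out.frame["il_6"]), [-1.224744871, 0.0, 1.224744871], atol=1e-8
    )
    # constant columns become all zeros via the sd floor
    assert (out.frame[other] == 0.0).all().all()


def test_standardize_uses_train_statistics(small_cohort):
    tr, va, te = split_cohort(small_cohort, seed=0)
    (tr_s, va_s), scaler = standardize(tr, va)
    col = tr_s.factor_columns[0]
    assert tr_s.frame[col].mean() == pytest.approx(0.0, abs=1e-9)
    manual = (va.frame[col] - scaler.mean[col]) / scaler.std[col]
    np.testing.assert_allclose(va_s.frame[col].to_numpy(), manual.to_numpy())


# -- mixing ------------------------------------------------------------------

def test_mix_fraction_extremes(small_cohort, sparse_cohort):
    only_src = mix_pretraining(small_cohort, sparse_cohort, 1.0, seed=0)
    assert only_src.n_patient_days == small_cohort.n_patient_days
    only_tgt = mix_pretraining(small_cohort, sparse_cohort, 0.0, seed=0)
    assert only_tgt.n_patient_days == sparse_cohort.n_patient_days


def test_mix_source_share_close_to_requested():
    from prcrs.synth import GeneratorConfig, generate_cohort

    src = generate_cohort(GeneratorConfig(n_patients=120, seed=1), origin="source")
    tgt = generate_cohort(GeneratorConfig(n_patients=40, seed=2), origin="target")
    mixed = mix_pretraining(src, tgt, 0.6, seed=0)
    src_days = mixed.frame["patient_id"].str.startswith("S").sum()
    share = src_days / mixed.n_patient_days
    # within one patient's worth of days of the requested share
    max_stay = src.frame.groupby("patient_id").size().max()
    assert abs(share - 0.6) <= max_stay / mixed.n_patient_days + 1e-9


def test_mix_bad_fraction(small_cohort, sparse_cohort):
    with pytest.raises(ValueError):
        mix_pretraining(small_cohort, sparse_cohort, 1.5)


# -- sequences ---------------------------------------------------------------

def test_cohort_to_sequences_shapes(small_cohort):
    (std,), _ = standardize(impute_by_grade_median(small_cohort))
    for lead in (0, 1, 2, 3):
        for s in cohort_to_sequences(std, lead):
            assert s.matrix.shape[0] == len(s.labels) + lead
            assert set(np.unique(s.labels)) <= {0, 1}
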