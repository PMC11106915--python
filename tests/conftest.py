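import numpy as np
import pandas as pd
import pytest

from prcrs.data import Cohort
from prcrs.network import ModelConfig
from prcrs.schema import DEFAULT_SCHEMA
from prcrs.synth import generate_cohort, target_cohort_config


def make_cohort_frame(rows):
    """rows: (patient_id, day, grade, dict of factor values); other factors NaN."""
    factors = DEFAULT_SCHEMA.all_factors()
    data = []
    for pid, day, grade, vals in rows:
        rec = {"patient_id": pid, "day": day, "grade": grade}
        rec.update({f: np.nan for f in factors})
        rec.update(vals)
        data.append(rec)
    return pd.DataFrame(data, columns=["patient_id", "day", "grade", *factors])


@pytest.fixture(scope="session")
def small_cohort():
    """Dense 20-patient synthetic target cohort (no missing values)."""
    return generate_cohort(target_cohort_config(20, seed=42, missing_rate=0.0))


@pytest.fixture(scope="session")
def sparse_cohort():
    """20-patient cohort with 15% missing values."""
    return generate_cohort(target_cohort_config(20, seed=43, missing_rate=0.15))


@pytest.fixture
def tiny_model_cfg():
    return ModelConfig(
        n_features=42, d_model=8, n_heads=2, n_blocks_per_level=1,
        unet_depth=1, dropout=0.0, seed=7,
    )
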