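import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from glygfr.cohort import Cohort

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from glygfr.simulate import GenerativeConfig, simulate_cohort
from glygfr.specio import load_builtin


@pytest.fixture(scope="session")
def pima_spec():
    return load_builtin("pima")


@pytest.fixture(scope="session")
def default_sim():
    """One default-size simulated cohort (269 subjects, 2798 exams)."""
    return simulate_cohort(seed=11)


def small_config(**overrides) -> GenerativeConfig:
    """A scaled-down generator configuration for fast tests."""
    cfg = GenerativeConfig()
    cfg.n_subjects = 60
    cfg.total_exams = 600
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cohort(small_config(), seed=23)


def make_cohort(rows) -> Cohort:
    """Build a cohort from (subject_id, exam_index, age, sex, scr[, agfr]) tuples.

    Remaining covariates get fixed plausible values.
    """
    recs = []
    for row in rows:
        sid, idx, age, sex, scr = row[:5]
        agfr = row[5] if len(row) > 5 else np.nan
        recs.append(
            {
                "subject_id": sid, "exam_index": idx, "age_years": age,
                "sex": sex, "height_m": 1.65, "weight_kg": 90.0,
                "scr_mg_dl": scr, "fpg_mg_dl": 180.0, "hba1c_pct": 9.0,
                "duration_years": 10.0, "mgfr_ml_min": np.nan,
                "agfr_ml_min_1p73": agfr,
            }
        )
    return Cohort(pd.DataFrame(recs))
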