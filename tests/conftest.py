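import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from whtr_cutoffs.cohort import Cohort
from whtr_cutoffs.synthetic import generate_reference_tables

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refs():
    """Synthetic (growth, BP) reference tables shared across the suite."""
    return generate_reference_tables(seed=11)


@pytest.fixture(scope="session")
def growth_ref(refs):
    return refs[0]


@pytest.fixture(scope="session")
def bp_ref(refs):
    return refs[1]


def make_cohort_frame(rows):
    """Build a cohort frame from dicts, filling unspecified fields with
    benign in-range defaults."""
    defaults = dict(
        age_years=10,
        sex="male",
        height_cm=140.0,
        weight_kg=35.0,
        waist_cm=60.0,
        sbp_mmHg=100.0,
        dbp_mmHg=60.0,
        tg_mgdl=80.0,
        hdl_mgdl=55.0,
        fbg_mgdl=85.0,
    )
    records = []
    for i, row in enumerate(rows):
        rec = {"id": f"r{i:03d}", **defaults, **row}
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def small_cohort():
    """Ten healthy-range children spanning ages and sexes."""
    rows = [
        {"age_years": a, "sex": s, "height_cm": 120.0 + 4 * (a - 6), "waist_cm": (120.0 + 4 * (a - 6)) * w}
        for a, s, w in [
            (6, "male", 0.44), (8, "female", 0.46), (10, "male", 0.48),
            (12, "female", 0.50), (14, "male", 0.52), (16, "female", 0.45),
            (18, "male", 0.47), (9, "female", 0.49), (11, "male", 0.51),
            (13, "female", 0.43),
        ]
    ]
    return Cohort(make_cohort_frame(rows), label="small")
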