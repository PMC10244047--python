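import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from emrsynth import CohortDataset, ScenarioConfig, simulate_study


ELIGIBILITY_CRITERIA = [
    {"field": "age_years", "op": "range", "args": [40, 94]},
    {"field": "baseline_score", "op": "range", "args": [10, 26]},
    {"field": "diagnosis_code", "op": "in_set", "args": ["AD", "AD_CVD"]},
    {"field": "has_caregiver", "op": "equals", "args": True},
    {"field": "has_other_major_psychiatric_disorder", "op": "equals", "args": False},
]


@pytest.fixture
def criteria():
    return ELIGIBILITY_CRITERIA


@pytest.fixture
def tiny_cohort():
    """Hand-written three-subject cohort."""
    records = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b", "c"],
            "time_years": [-0.5, 1.0, -1.0, 3.0, 0.25],
            "numerator": [24, 30, 23, 20, 24],
            "denominator": [29, 30, 23, 30, 24],
        }
    )
    baselines = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c"],
            "age_years": [70.0, 95.0, 50.0],
            "baseline_score": [20.0, 15.0, 27.0],
            "diagnosis_code": ["AD", "AD", "AD_CVD"],
            "has_caregiver": [True, True, True],
            "has_other_major_psychiatric_disorder": [False, False, False],
        }
    )
    return CohortDataset(records=records, baselines=baselines)


@pytest.fixture(scope="session")
def small_study():
    """One simulated study replicate at reduced size, shared across tests."""
    scenario = ScenarioConfig(n1=400, k=4, n2=120, seed=42)
    return simulate_study(scenario, seed=42)
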