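import numpy as np
import pandas as pd
import pytest

from tbal.data_model import Cohort, VariableSpec
from tbal.preprocess import preprocess_cohort
from tbal.synthetic import SimConfig, simulate_cohort


@pytest.fixture()
def tiny_dictionary():
    return {
        "hr": VariableSpec("hr", "numeric", "median", "linear"),
        "lact": VariableSpec("lact", "numeric", "median", "linear"),
        "rhythm": VariableSpec("rhythm", "categorical", "mode", "locf",
                               categories=("sinus", "afib", "missing")),
    }


@pytest.fixture()
def tiny_cohort(tiny_dictionary):
    stays = pd.DataFrame([
        {"stay_id": "a", "patient_id": "p1", "icu_los_h": 48.0,
         "death_time_h": 30.0, "age_years": 50, "sex": "female",
         "race": "white"},
        {"stay_id": "b", "patient_id": "p1", "icu_los_h": 100.0,
         "death_time_h": np.nan, "age_years": 50, "sex": "female",
         "race": "white"},
        {"stay_id": "c", "patient_id": "p2", "icu_los_h": 24.0,
         "death_time_h": np.nan, "age_years": 71, "sex": "male",
         "race": "black"},
    ])
    events = pd.DataFrame([
        ("a", 0.2, "hr", 80.0), ("a", 1.2, "hr", 90.0),
        ("a", 2.0, "lact", 1.5), ("a", 5.5, "rhythm", "afib"),
        ("b", 0.1, "hr", 70.0), ("b", 50.0, "lact", 0.9),
        ("b", 99.0, "rhythm", "sinus"),
        ("c", 3.0, "hr", 65.0), ("c", 10.0, "hr", 72.0),
    ], columns=["stay_id", "time_h", "variable", "value"])
    cohort = Cohort(stays=stays, events=events, dictionary=tiny_dictionary)
    cohort.validate()
    return cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated cohort shared across test modules."""
    config = SimConfig(n_patients=80, seed=5)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_prep(small_sim):
    cohort, _ = small_sim
    from tbal.data_model import filter_eligible
    eligible, _ = filter_eligible(cohort)
    return eligible, preprocess_cohort(eligible)
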