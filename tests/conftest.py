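import numpy as np
import pandas as pd
import pytest

from pyrotier import default_config, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 451-patient synthetic cohort, shared across tests."""
    cohort, truth = simulate_cohort(default_config(seed=11))
    return cohort, truth


@pytest.fixture()
def small_cohort_frame():
    """Three-row, fully valid cohort table."""
    return pd.DataFrame({
        "patient_id": ["a", "b", "c"],
        "cpg76": [2.0, 30.0, 8.0], "cpg77": [3.0, 32.0, 9.0],
        "cpg78": [2.5, 28.0, 10.0], "cpg79": [2.5, 30.0, 9.0],
        "mean_meth": [2.5, 30.0, 9.0],
        "age": [55.0, 62.0, 70.0],
        "sex": ["male", "female", "male"],
        "preop_ps": [0, 1, 2],
        "resection": ["GTR", "STR", "biopsy"],
        "os_months": [10.0, 30.0, 15.0],
        "event": [1, 1, 0],
    })


def random_censored_dataset(rng, n):
    """Random survival data with ties in times and predictions."""
    times = rng.integers(1, 12, size=n).astype(float)
    events = rng.integers(0, 2, size=n)
    preds = rng.integers(0, 6, size=n).astype(float)
    return times, events, preds
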