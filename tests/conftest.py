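import numpy as np
import pandas as pd
import pytest

from ecgtree.synthetic import default_specs, simulate_cohort
from ecgtree.preprocess import preprocess_collection


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient cohort with rendered ECGs (used across preprocessing tests)."""
    specs = default_specs()
    cohort, ecgs = simulate_cohort(specs, n_patients=120, seed=7)
    return cohort, ecgs, specs


@pytest.fixture(scope="session")
def small_beats(small_cohort):
    cohort, ecgs, specs = small_cohort
    beats, ids, skipped = preprocess_collection(ecgs)
    pids = cohort.set_index("record_id").loc[ids, "patient_id"].to_numpy()
    truth = cohort.set_index("record_id").loc[ids, "true_group"].to_numpy()
    return beats, ids, pids, truth
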