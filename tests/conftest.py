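import numpy as np
import pandas as pd
import pytest

import cd4traj as c


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient cohort at the published population values (seed 42)."""
    return c.generate_cohort(c.default_published_config(n_patients=200, seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """10k-patient cohort for Monte-Carlo moment and calibration checks."""
    return c.generate_cohort(c.default_published_config(n_patients=10_000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_visits(records):
    """Long-format visit table from (pid, sex, age_group, age, t, cd4) tuples."""
    return pd.DataFrame(
        records,
        columns=["patient_id", "sex", "age_group", "age_at_init", "visit_time_years", "cd4_count"],
    )
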