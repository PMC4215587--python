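import numpy as np
import pandas as pd
import pytest

from phosphosig import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by read-only tests."""
    cfg = SimConfig(
        n_probes=300,
        n_samples_per_group=40,
        n_de_probes=30,
        n_prognostic=5,
        beta_range=(0.6, 1.0),
        probe_sd=0.5,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_matrix():
    return pd.DataFrame(
        np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 5.5, 6.0]]),
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
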