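import numpy as np
import pytest

from glp.encoding import default_threshold_table
from glp.interpolation import ObservationSequence
from glp.synthetic import CohortConfig, simulate_pretext_cohort


@pytest.fixture(scope="session")
def table():
    return default_threshold_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A small single-marker pretraining cohort used across training tests."""
    cfg = CohortConfig(n_patients=30, seed=42, markers=("LDL-c",),
                       span_months_range=(18, 40))
    series, trajectories = simulate_pretext_cohort(cfg)
    return cfg, series, trajectories


@pytest.fixture
def worked_obs():
    """The worked framing example: observed months {0,3,6,9,12,15,20,26}."""
    months = np.array([0, 3, 6, 9, 12, 15, 20, 26])
    values = 100.0 + np.arange(len(months), dtype=float)
    return ObservationSequence(months, values)


def random_observations(rng, n_min=2, n_max=12, span_max=40):
    """Random strictly increasing integer months with positive values."""
    n = int(rng.integers(n_min, n_max + 1))
    months = np.sort(rng.choice(span_max + 1, size=n, replace=False))
    values = np.exp(rng.normal(4.0, 0.3, size=n))
    return ObservationSequence(months, values)
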