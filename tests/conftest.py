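import numpy as np
import pytest

from vmhrv import CohortConfig, RRSeries, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_series():
    """100 perfectly regular 1000 ms beats."""
    return RRSeries(np.full(100, 1000.0))


@pytest.fixture(scope="session")
def small_signal_cohort():
    """A clean 10-subject, 1-game cohort with full signal synthesis."""
    cfg = CohortConfig(n_subjects=10, games=("Simple",), seed=7)
    table, truth, series = generate_cohort(cfg, signals=True)
    return cfg, table, truth, series
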