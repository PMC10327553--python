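import warnings

import numpy as np
import pytest

from pupilrqa import CohortSpec, RunConfig, gen_cohort, preprocess_trace
from pupilrqa.traces import WindowScheme


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """Reduced cohort for fast end-to-end tests: short traces, few subjects."""
    return CohortSpec(
        n_solvers=5, n_nonsolvers=7, duration_s=80.0, solver_epoch=(40.0, 8.0), seed=7,
        gap_rate=4.0, dropout_rate=0.05, outlier_rate=3.0,
    )


@pytest.fixture(scope="session")
def small_scheme() -> WindowScheme:
    """20-window layout over the last 48 s (500/100 at 50 Hz)."""
    return WindowScheme(window=500, step=100, last_n_seconds=48.0)


@pytest.fixture(scope="session")
def small_clean_traces(small_cohort_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [preprocess_trace(t) for t in gen_cohort(small_cohort_spec)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
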