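import numpy as np
import pytest

from latentflow import SubjectSeries, generate_cohort
from latentflow.synthetic import CohortParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for plumbing tests (not powered for group statistics)."""
    params = CohortParams(n_controls=4, n_patients=6, n_roi=16, n_frames=120)
    return generate_cohort(params, seed=11)


@pytest.fixture(scope="session")
def desk_cohort():
    """Default desk-profile cohort (30 controls, 60 patients, 50 ROIs)."""
    return generate_cohort(seed=101)


@pytest.fixture()
def random_series(rng):
    def make(n_roi=10, n_frames=100, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        return SubjectSeries(local.normal(size=(n_roi, n_frames)))
    return make
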