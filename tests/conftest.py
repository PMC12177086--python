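import numpy as np
import pytest

from sonomil.phantom import CohortSpec, simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient phantom cohort with default (planted-effect) settings."""
    spec = CohortSpec(n_patients=30, seed=123)
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_on_disk(small_cohort, tmp_path_factory):
    spec, patients = small_cohort
    root = tmp_path_factory.mktemp("cohort")
    manifest = write_cohort(patients, root, train_ratio=0.8)
    return root, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
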