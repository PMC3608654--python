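import numpy as np
import pandas as pd
import pytest

from ezmap import (CohortStack, SyntheticSpec, VolumeGrid, cohort_from_arrays,
                   ellipsoid_mask, generate_cohorts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mask():
    return ellipsoid_mask((16, 16, 16))


def make_covariates(n, rng, prefix="s"):
    return pd.DataFrame({
        "subject_id": [f"{prefix}{i}" for i in range(n)],
        "age": rng.uniform(20, 60, n).round(1),
        "sex": rng.choice(["F", "M"], n),
        "education": rng.uniform(8, 22, n).round(1),
    })


def make_cohort(rng, n, mask, sd=0.05, baseline=0.45, role="reference"):
    """iid-Gaussian cohort (no spatial correlation) on the given mask."""
    arrays = baseline + sd * rng.standard_normal((n, *mask.shape))
    return cohort_from_arrays(arrays, mask,
                              covariates=make_covariates(n, rng, role[:3]),
                              role_label=role)


@pytest.fixture
def gaussian_cohort(rng, small_mask):
    return make_cohort(rng, 21, small_mask)


@pytest.fixture(scope="session")
def smooth_study():
    """One shared smooth synthetic study for the slower integration tests."""
    spec = SyntheticSpec(shape=(24, 24, 24), n_reference=21, n_test_controls=10,
                         n_patients=8, seed=2024)
    reference, controls, patients, truths = generate_cohorts(spec)
    return spec, reference, controls, patients, truths
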