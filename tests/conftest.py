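import numpy as np
import pytest

import wmhnet as w


@pytest.fixture(scope="session")
def small_spec() -> w.CohortSpec:
    return w.CohortSpec(n_subjects=48, n_regions=10, n_timepoints=100, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    subjects, labels = w.generate_subjects(small_spec)
    series = w.generate_timeseries(small_spec, labels, subjects)
    return subjects, labels, series


@pytest.fixture(scope="session")
def covariates(small_cohort):
    subjects, _, _ = small_cohort
    age = np.array([s.age for s in subjects])
    sex = np.array([1.0 if s.sex == "male" else 0.0 for s in subjects])
    return age, sex
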