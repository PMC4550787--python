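import numpy as np
import pytest

from osascreen.synthetic import (Demographics, SubjectProfile,
                                 sample_demographics)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151114)


@pytest.fixture(scope="session")
def demographics():
    return sample_demographics("severe", np.random.default_rng(5))


@pytest.fixture(scope="session")
def severe_profile(demographics):
    return SubjectProfile(subject_id="T001", severity="severe", true_ahi=40.0,
                          demographics=demographics, seed=101)


@pytest.fixture(scope="session")
def normal_profile():
    d = sample_demographics("normal", np.random.default_rng(6))
    return SubjectProfile(subject_id="T002", severity="normal", true_ahi=2.0,
                          demographics=d, seed=102)
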