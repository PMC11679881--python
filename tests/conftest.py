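import numpy as np
import pytest
from hypothesis import settings

from shetca.simulate import default_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study():
    """The default seeded synthetic study, with rendered densitograms."""
    return default_study(seed=1)


@pytest.fixture(scope="session")
def study_matrices():
    """Lighter variant without densitogram rendering."""
    return default_study(seed=1, render=False)


@pytest.fixture(scope="session")
def pipeline_matrix(study):
    """Integration matrix recovered from the rendered densitograms."""
    from shetca.peaks import integrate_profiles

    return integrate_profiles(study.densitograms, study.windows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
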