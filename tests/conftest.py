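import numpy as np
import pytest

from sulfoc.calibration import SulfurizationModel
from sulfoc.synthetic import GeneratorConfig, generate_profile


@pytest.fixture(scope="session")
def default_profile():
    """The generator's default 40-sample synthetic profile (seed 0)."""
    return generate_profile(GeneratorConfig())


@pytest.fixture(scope="session")
def small_ensemble():
    """A 60-member calibrated ensemble shared by scenario tests."""
    return SulfurizationModel().fit(n=60, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
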