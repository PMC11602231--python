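import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colnet.hydro_align import GapParams, build_substitution_matrix, load_scale
from colnet.synthetic import SynthParams, generate_dataset

settings.register_profile(
    "colnet",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("colnet")


@pytest.fixture(scope="session")
def eisenberg_matrix():
    return build_substitution_matrix(load_scale())


@pytest.fixture(scope="session")
def gaps():
    return GapParams()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset: 6 families, 44 chains, fixed seed."""
    return generate_dataset(SynthParams(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
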