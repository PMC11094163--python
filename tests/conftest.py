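import pytest

from pdtsim.datasets import ResponseSurfaceParams, generate_dataset
from pdtsim.surrogate import ViabilitySurrogate


@pytest.fixture(scope="session")
def default_dataset():
    """Default factorial dataset: sigma = 0.08, seed 1."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    """Surrogate fitted on the default dataset with seed 1."""
    return ViabilitySurrogate(default_dataset).fit(seed=1)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_dataset(ResponseSurfaceParams(noise_sd=0.0), seed=1)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_dataset):
    return ViabilitySurrogate(noiseless_dataset).fit(seed=1, epochs=2000)
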