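import numpy as np
import pytest

import confspec as cs


@pytest.fixture(scope="session")
def three_basins():
    return cs.default_basins()


@pytest.fixture(scope="session")
def small_run(three_basins):
    """A modest labelled synthetic ensemble shared across tests."""
    ensemble, truth = cs.generate_ensemble(three_basins, 300, seed=7)
    return ensemble, truth


@pytest.fixture(scope="session")
def small_projection(small_run):
    """SOAP -> 2-component PCA projection of the shared ensemble."""
    ensemble, _truth = small_run
    values = cs.SoapDescriptor().fit(ensemble).transform(ensemble)
    return cs.pca(values, n_components=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
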