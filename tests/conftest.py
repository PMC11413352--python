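import numpy as np
import pytest

import eapnet as e


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def specs():
    """Calibrated (control, schizophrenia) generating models."""
    return e.default_specs()


@pytest.fixture(scope="session")
def sz_sample(specs):
    _, sz = specs
    return e.simulate(sz, 663, seed=42)


@pytest.fixture(scope="session")
def sz_std(sz_sample):
    return e.standardize(sz_sample)
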