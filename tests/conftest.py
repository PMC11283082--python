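import numpy as np
import pytest

import serialdep as sd


@pytest.fixture(scope="session")
def paper_like_dataset():
    """Default 21-participant, 400-trial simulated experiment."""
    return sd.generate_dataset(sd.SimConfig(seed=0))


@pytest.fixture(scope="session")
def cleaned(paper_like_dataset):
    return sd.preprocess(paper_like_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
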