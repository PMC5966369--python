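import numpy as np
import pytest

from chemstitch.synthetic import SynthParams, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 20-document synthetic corpus shared by read-only tests."""
    return generate_corpus(SynthParams(n_documents=20, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
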