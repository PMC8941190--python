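import pytest

from dendromux.threshold import load_registry
from dendromux.toy import make_toy_neuron


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_neuron()
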