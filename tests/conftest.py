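import numpy as np
import pytest

from pairscreen import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def ethanol_bits():
    """Substructure-key fingerprint of ethanol, computed once per session."""
    from pairscreen import compute_fingerprint

    return compute_fingerprint("CCO").bits


@pytest.fixture(scope="session")
def toy_world():
    """A small deterministic two-cluster world shared by read-only tests."""
    return generate_world(SyntheticConfig(n_drugs=12, n_diseases=12, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
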