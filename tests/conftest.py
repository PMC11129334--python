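import numpy as np
import pytest

from chicap import demo_panel, miniature_reference_signatures, synthetic_signature_matrix


@pytest.fixture(scope="session")
def panel():
    return demo_panel()


@pytest.fixture(scope="session")
def mini_sigs():
    """Bundled synthetic reference set with named signatures."""
    return miniature_reference_signatures()


@pytest.fixture(scope="session")
def three_sigs():
    """Three peaked synthetic signatures for recovery experiments."""
    return synthetic_signature_matrix(("S_a", "S_b", "S_c"), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
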