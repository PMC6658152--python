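import numpy as np
import pytest

from fundusgraph.synthetic import TreeSpec, generate_vessel_tree


@pytest.fixture(scope="session")
def synthetic_image():
    """One deterministic synthetic fundus image shared across tests."""
    return generate_vessel_tree(TreeSpec(image_size=384, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
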