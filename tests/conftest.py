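import numpy as np
import pytest

import cox1intron as cx


@pytest.fixture
def rng():
    return np.random.default_rng(20170320)


@pytest.fixture(scope="session")
def demo_bundle():
    """One simulated demo dataset shared by read-only tests."""
    return cx.simulate(cx.demo_spec(seed=7))


@pytest.fixture(scope="session")
def demo_reference(demo_bundle):
    return cx.ReferenceCDS(id=demo_bundle.reference.id,
                           seq=demo_bundle.reference.seq)
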