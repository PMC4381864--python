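import numpy as np
import pytest

from strapkin import SynthConfig, make_reference_pr


@pytest.fixture(scope="session")
def refs():
    """Default open/closed reference P(r) pair on a shared grid."""
    return make_reference_pr(cfg=SynthConfig(seed=42))


@pytest.fixture(scope="session")
def open_ref(refs):
    return refs[0]


@pytest.fixture(scope="session")
def closed_ref(refs):
    return refs[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
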