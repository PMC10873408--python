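import numpy as np
import pytest

from nutrigeom.design import load_packaged_design
from nutrigeom.simulate import default_scenario


@pytest.fixture(scope="session")
def design():
    """The packaged ten-diet reference design (57 samples)."""
    return load_packaged_design()


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic study shared across tests (fixed seed)."""
    return default_scenario(11, n_genes=500, n_splice_genes=150)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
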