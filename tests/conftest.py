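import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ndmmkit as nk
from ndmmkit.simulate import DEFAULT_CLADE_SIZES

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tree32():
    """Ultrametric 32-tip tree with the study's clade structure."""
    phy = nk.simulate_tree(32, DEFAULT_CLADE_SIZES, seed=101)
    assert phy.is_ultrametric()
    return phy


@pytest.fixture(scope="session")
def tree16():
    return nk.simulate_tree(16, seed=202)


@pytest.fixture(scope="session")
def full_library():
    """Candidate library spanning the observed chemical space."""
    return nk.build_library(
        nk.LibraryConfig(
            chain_lengths=tuple(range(3, 12)),
            unsaturated_lengths=(7,),
            omega_lengths=(3,),
            heads=("UB", "UP"),
            dimers=True,
            heads_on_dimers=True,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
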