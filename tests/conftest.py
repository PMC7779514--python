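import numpy as np
import pytest

import gamespace as gs


@pytest.fixture(scope="session")
def space():
    """The 144 canonical two-player games (expensive bits cached per session)."""
    return gs.enumerate_two_player_space()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def named():
    """Catalog games by name, in raw (non-canonical) catalog form."""
    return {name: entry.game for name, entry in gs.load_catalog().items()}
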