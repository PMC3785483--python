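import numpy as np
import pytest

from gatewave.structio import RadiusTable, assign_radii
from gatewave.synthfix import ChannelSpec, make_two_state_channel


@pytest.fixture(scope="session")
def channel_pair():
    """Default two-state channel fixture (closed, open), radii assigned."""
    closed, opened = make_two_state_channel(ChannelSpec())
    assign_radii(closed)
    assign_radii(opened)
    return closed, opened


@pytest.fixture(scope="session")
def closed_channel(channel_pair):
    return channel_pair[0]


@pytest.fixture(scope="session")
def open_channel(channel_pair):
    return channel_pair[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20130927)
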