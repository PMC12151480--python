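import numpy as np
import pytest

from maskflow.channel import FabricModel, FluidProperties
from maskflow.gaps import apply_gaps, mean_face_gaps
from maskflow.geometry import (
    CavitySpec,
    ChannelGeometry,
    ChannelLayout,
    MaskSpec,
    build_channels,
)


@pytest.fixture(scope="session")
def mask():
    return MaskSpec()


@pytest.fixture(scope="session")
def cavity(mask):
    return CavitySpec.default_for(mask)


@pytest.fixture(scope="session")
def default_layout():
    return ChannelLayout()


@pytest.fixture(scope="session")
def small_layout():
    """6 half-model channels: keeps network tests fast."""
    return ChannelLayout(n_nose=4, n_chin=4, n_cheek_per_side=2)


@pytest.fixture(scope="session")
def small_channels(mask, cavity, small_layout):
    return build_channels(mask, cavity, small_layout)


@pytest.fixture(scope="session")
def small_gapped(mask, cavity, small_layout):
    chans = build_channels(mask, cavity, small_layout)
    return apply_gaps(chans, mean_face_gaps(chans, seed=7))


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def fabric500():
    return FabricModel(c_k=500.0)


def make_channel(heights, width=0.0143, length=0.0471, region="nose",
                 index=1, exit_y=0.0686):
    """Stand-alone channel for solver unit tests."""
    return ChannelGeometry(index=index, region=region, width=width,
                           edge="top", exit_point=(0.0, exit_y),
                           length=length, heights=np.asarray(heights, float))


@pytest.fixture
def uniform_channel():
    return make_channel(np.full(101, 3.0e-3))


@pytest.fixture
def tapered_channel():
    x = np.linspace(0.0, 1.0, 101)
    K = 3.0e-3 * (1.0 + 0.15 * np.cos(2 * np.pi * x) + 0.2 * x)
    return make_channel(K)
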