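import numpy as np
import pytest

import ptxkit as pk


@pytest.fixture(scope="session")
def phantom_small():
    """Coarse phantom for unit tests: 24x24x20 grid at 8 mm."""
    return pk.generate_phantom(
        grid_shape=(24, 24, 20),
        voxel_size_mm=(8.0, 8.0, 8.0),
        body_semiaxes_mm=(80.0, 60.0),
        roi_spec={"semiaxes_mm": (34.0, 36.0, 48.0), "center_mm": (28.0, 0.0, 0.0)},
        seed=0,
    )


@pytest.fixture(scope="session")
def b1_small(phantom_small):
    """Ten-element array on the small phantom."""
    return pk.generate_b1_maps(
        phantom_small,
        ring_spec=pk.RingSpec((3, 4, 3), (-110.0, 0.0, 110.0), 320.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def roi_small(phantom_small):
    return phantom_small.roi_mask


@pytest.fixture(scope="session")
def phantom_default():
    """The default 48x48x40 / 4 mm phantom used for the full-scale checks."""
    return pk.generate_phantom(seed=1)


@pytest.fixture(scope="session")
def b1_default(phantom_default):
    """Default 32-element array with the four unstable channels removed."""
    b1 = pk.generate_b1_maps(phantom_default, seed=1)
    return pk.apply_channel_failures(b1, [11, 20, 24, 32])


@pytest.fixture(scope="session")
def make_random_b1():
    """Factory for unstructured random complex maps (metric/oracle tests)."""

    def _make(phantom, n_channels, seed):
        rng = np.random.default_rng(seed)
        shape = (n_channels,) + tuple(phantom.grid_shape)
        maps = rng.normal(size=shape + (2,))
        maps = maps[..., 0] + 1j * maps[..., 1]
        return pk.B1MapSet(maps, phantom, np.ones(n_channels, dtype=bool))

    return _make
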