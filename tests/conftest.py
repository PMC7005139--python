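import numpy as np
import pytest

from hbdot.geometry import (build_probe_layout, build_sensitivity,
                            build_voxel_grid, default_layout_config)


@pytest.fixture(scope="session")
def small_layout():
    """Single 4x4 checkerboard array (24 short + 24 long channels)."""
    return build_probe_layout(default_layout_config(n_arrays=1))


@pytest.fixture(scope="session")
def small_grid(small_layout):
    return build_voxel_grid(small_layout)


@pytest.fixture(scope="session")
def small_sensitivity(small_layout, small_grid):
    return build_sensitivity(small_layout, small_grid)


@pytest.fixture(scope="session")
def default_layout():
    """Four-array montage (96 short + 96 long channels)."""
    return build_probe_layout(default_layout_config(n_arrays=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
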