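import numpy as np
import pytest

import tubetomo as tt


@pytest.fixture(scope="session")
def small_tube_spec():
    """Short featureless canonical tube that fits a 40-voxel box."""
    return tt.canonical_tube_spec(length=24.0)


@pytest.fixture(scope="session")
def small_tube_volume(small_tube_spec):
    return tt.rasterize_phantom(small_tube_spec, 40)


@pytest.fixture(scope="session")
def structured_tube_volume():
    """Three-strand tube: rotationally asymmetric, good for alignment tests."""
    return tt.rasterize_phantom(
        tt.canonical_tube_spec(length=24.0, n_strands=3), 40)


@pytest.fixture(scope="session")
def default_geometry():
    return tt.TiltGeometry()


@pytest.fixture(scope="session")
def coarse_geometry():
    """+/-64 degrees at 3-degree steps: same wedge, fewer projections."""
    return tt.TiltGeometry(increment=3.0)
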