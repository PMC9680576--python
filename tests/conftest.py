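"""Shared fixtures: a miniature skull phantom and DRRs sized for fast tests.

The mini skull keeps every structural element of the full phantom (shell,
fill, BB, sinus cavities, landmark nodules) at ~40% linear scale so DRR
and registration tests run in milliseconds-to-seconds.
"""

import numpy as np
import pytest

from bevroi.phantom import PhantomSpec, generate_skull_phantom, remove_bb_region
from bevroi.projection import BeamGeometry, compute_drr
from bevroi.registration import preprocess


MINI_KW = dict(
    outer_semi_axes=(30.0, 38.0, 32.0),
    shell_thickness=4.0,
    voxel_spacing=1.0,
    seed=3,
)


@pytest.fixture(scope="session")
def mini_spec():
    return PhantomSpec(**MINI_KW)


@pytest.fixture(scope="session")
def mini_volume(mini_spec):
    return generate_skull_phantom(mini_spec)


@pytest.fixture(scope="session")
def mini_reference(mini_volume, mini_spec):
    # BB-removal box scaled to the mini skull so it stays interior
    return remove_bb_region(mini_volume, (20, 20, 16), mini_spec.fill_hu)


@pytest.fixture(scope="session")
def mini_geometry():
    return BeamGeometry(0.0, 0.0, sid_mm=1500.0, panel_pitch_mm=1.2)


@pytest.fixture(scope="session")
def mini_drr(mini_reference, mini_geometry):
    return compute_drr(mini_reference, mini_geometry, (128, 128))


@pytest.fixture(scope="session")
def mini_fixed(mini_drr):
    return preprocess(mini_drr.pixels)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
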