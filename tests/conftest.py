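import numpy as np
import pytest

from megmyelin import ConductorModel, dipole_field, make_sensor_array
from megmyelin.vbecd import auditory_priors


@pytest.fixture(scope="session")
def conductor():
    return ConductorModel()


@pytest.fixture(scope="session")
def mag_array():
    """64-channel magnetometer cap (no gradiometer baseline)."""
    return make_sensor_array(64, 120.0, baseline_mm=None)


@pytest.fixture(scope="session")
def grad_array():
    """275-channel axial-gradiometer helmet."""
    return make_sensor_array(275, 120.0)


def tangential_unit(location, seed=0):
    """Deterministic unit vector orthogonal to the radial direction."""
    radial = location / np.linalg.norm(location)
    v = np.cross(radial, [0.0, 0.0, 1.0])
    n = np.linalg.norm(v)
    if n < 1e-9:
        v = np.cross(radial, [1.0, 0.0, 0.0])
        n = np.linalg.norm(v)
    return v / n


def two_dipole_topography(array, conductor, magnitudes=(40.0, 25.0), jitter_seed=None):
    """Noiseless bilateral topography with known tangential dipoles.

    Returns (topography, locations (2,3), moment vectors (2,3)).
    """
    pri = auditory_priors()
    locs = pri.location_means_mm.copy()
    if jitter_seed is not None:
        locs = locs + np.random.default_rng(jitter_seed).normal(0, 3.0, locs.shape)
    topo = np.zeros(array.n_channels)
    mvecs = np.empty((2, 3))
    for d in range(2):
        mvecs[d] = magnitudes[d] * tangential_unit(locs[d])
        topo += dipole_field(locs[d], mvecs[d], conductor, array)
    return topo, locs, mvecs
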