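import numpy as np
import pytest

from aortacs.phantom import (
    PhantomSpec,
    RadialProfile,
    build_phantom,
    coil_sensitivities,
    default_spec,
    simulate_acquisition,
)
from aortacs.sampling import SamplingMask, full_mask


def small_spec(**overrides) -> PhantomSpec:
    """Compact phantom (48x48x16) with reference structures pulled inward,
    for tests where reconstruction cost matters more than anatomy scale."""
    defaults = dict(
        grid_shape=(48, 48, 16),
        lumen_radius_profile=RadialProfile.gaussian_bulge(7.0, 3.0, 6.0),
        ilt_thickness_profile=RadialProfile.gaussian_bulge(0.0, 3.0, 6.0),
        wall_thickness=2.0,
        ilt_type=2,
        muscle_offset=(20.0, 0.0),
        muscle_radius=6.0,
        spine_offset=(0.0, -22.0),
        spine_radius=7.0,
        noise_sd=0.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def all_ones_mask(ny: int, nz: int) -> SamplingMask:
    """Rectangular fully sampled mask (no elliptical truncation)."""
    return SamplingMask(
        grid=np.ones((ny, nz), dtype=bool),
        ellipse_semi_axes=(ny / 2.0, nz / 2.0),
        calib_semi_axes=(ny / 2.0, nz / 2.0),
        target_accel=1.0,
        achieved_fraction=1.0,
    )


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom(default_spec(seed=1))


@pytest.fixture(scope="session")
def coil_maps4(default_phantom):
    return coil_sensitivities(default_phantom.intensity.shape, 4, seed=2)


@pytest.fixture(scope="session")
def noiseless_full_acq(default_phantom, coil_maps4):
    ny, nz = default_phantom.intensity.shape[1:]
    return simulate_acquisition(default_phantom, coil_maps4, full_mask(ny, nz), noise_sd=0.0, seed=3)
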