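import numpy as np
import pytest

import gatedpet as gp


@pytest.fixture
def geo2mm():
    """Small isotropic 2 mm grid for fast mask arithmetic."""
    return gp.GridGeometry((32, 32, 32), (2.0, 2.0, 2.0))


@pytest.fixture
def sphere_mask_factory():
    """Rasterize a sphere mask (centre mm, radius mm) on a given geometry."""

    def make(geo, center, radius):
        cx, cy, cz = geo.voxel_centers()
        inside = (
            (cx[:, None, None] - center[0]) ** 2
            + (cy[None, :, None] - center[1]) ** 2
            + (cz[None, None, :] - center[2]) ** 2
            <= radius**2
        )
        return gp.BinaryMask(geo, inside)

    return make


@pytest.fixture(scope="session")
def torso16_static():
    """Noiseless static torso phantom, 16 cc sphere at SUV 7.9, FWHM 6 mm."""
    return gp.simulate_gated(gp.torso_preset("torso16"))


@pytest.fixture(scope="session")
def torso16_noisy_fwhm4():
    """Default-noise static torso phantom at FWHM 4 mm (threshold protocol)."""
    spec = gp.torso_preset("torso16", noise="gaussian_sqrt", psf_fwhm_mm=4.0, seed=0)
    return gp.simulate_gated(spec)
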