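"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

from stonewin import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def sphere_spec():
    """Noiseless 6.0 mm sphere, 800 HU on 0 HU background, 1.0 mm PSF,
    0.2 mm isotropic voxels — the canonical blooming phantom."""
    return PhantomSpec(
        semi_axes=(3.0, 3.0, 3.0),
        center=(7.0, 7.0, 7.0),
        stone_hu=800.0,
        background_hu=0.0,
        psf_fwhm=1.0,
        noise_sd=0.0,
        voxel_spacing=(0.2, 0.2, 0.2),
        volume_shape=(71, 71, 71),
        seed=0,
    )


@pytest.fixture(scope="session")
def sphere_volume(sphere_spec):
    vol, truth = render_phantom(sphere_spec)
    return vol, truth


@pytest.fixture(scope="session")
def sphere_seed_point(sphere_spec):
    return tuple(
        int(round(sphere_spec.center[a] / sphere_spec.voxel_spacing[a]))
        for a in range(3)
    )


@pytest.fixture(scope="session")
def coarse_sphere_volume():
    """Same sphere at clinical-ish 0.5 mm voxels, for faster protocol tests."""
    spec = PhantomSpec(
        semi_axes=(3.0, 3.0, 3.0),
        center=(8.0, 8.0, 8.0),
        stone_hu=800.0,
        background_hu=0.0,
        psf_fwhm=1.0,
        noise_sd=0.0,
        voxel_spacing=(0.5, 0.5, 0.5),
        volume_shape=(33, 33, 33),
        seed=0,
    )
    vol, truth = render_phantom(spec)
    return spec, vol, truth
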