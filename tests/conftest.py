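"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

from trabekit import phantom as ph


@pytest.fixture(scope="session")
def small_volume():
    """64-cube trabecular phantom at 30% BV/TV (medium texture)."""
    spec = ph.PhantomSpec(
        grid_shape=(64, 64, 64), seed=3, correlation_length_um=44.0
    )
    vol, field = ph.generate_trabecular_volume(spec)
    return spec, vol, field


@pytest.fixture(scope="session")
def slice_fixture():
    """A thin phantom and one stained slice for registration tests."""
    spec = ph.PhantomSpec(
        grid_shape=(32, 128, 128), seed=7, correlation_length_um=44.0
    )
    vol, _ = ph.generate_trabecular_volume(spec)
    rgb = ph.stain_slide(vol.voxels[16])
    gray = rgb @ np.array([0.2125, 0.7154, 0.0721])
    return vol, gray


@pytest.fixture(scope="session")
def stain_tiles():
    """Phantom stain tiles + class masks for segmentation training tests."""
    from trabekit.segmentation import tile_image

    spec = ph.PhantomSpec(grid_shape=(32, 128, 128), seed=2, correlation_length_um=44.0)
    vol, _ = ph.generate_trabecular_volume(spec)
    rng = np.random.default_rng(0)
    tiles, masks = [], []
    for z in range(0, 32, 5):
        m = vol.voxels[z]
        rgb = ph.stain_slide(m, noise_sd=0.03, rng=rng)
        tiles.append(tile_image(rgb, tile=32, overlap=8).tiles)
        masks.append(tile_image(m, tile=32, overlap=8).tiles)
    tiles = np.concatenate(tiles)
    masks = np.concatenate(masks)
    sel = np.random.default_rng(1).choice(len(tiles), 120, replace=False)
    return tiles[sel], masks[sel]
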