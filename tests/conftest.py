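"""Shared fixtures: small acquisition geometries and synthetic objects.

All fixtures are generated programmatically; nothing is read from disk.
"""

import numpy as np
import pytest
from scipy import ndimage

from conjclass.geometry import AcquisitionGeometry, Grid


@pytest.fixture(scope="session")
def geo_tiny():
    """8×8 scan, 32² window — fast toy for structural checks."""
    return AcquisitionGeometry(sample_pixel_pitch=0.65, scan_step=0.65,
                               scan_shape=(8, 8), detection_extent=0.65 * 32,
                               conjugate_distance=100.0)


@pytest.fixture(scope="session")
def geo_standard():
    """16×16 scan, 64² window — standard solver-scale geometry."""
    return AcquisitionGeometry(sample_pixel_pitch=0.65, scan_step=0.65,
                               scan_shape=(16, 16), detection_extent=0.65 * 64,
                               conjugate_distance=100.0)


def gauss_blobs(grid: Grid, sigma_px: float = 4.0, seed: int = 5, n: int = 4,
                halfspan_px: int = 6) -> np.ndarray:
    """Band-limited test object: a few Gaussian reflectors near the centre."""
    rng = np.random.default_rng(seed)
    o = np.zeros(grid.shape)
    ny, nx = grid.shape
    iy = rng.integers(ny // 2 - halfspan_px, ny // 2 + halfspan_px + 1, n)
    ix = rng.integers(nx // 2 - halfspan_px, nx // 2 + halfspan_px + 1, n)
    o[iy, ix] = 1.0
    o = ndimage.gaussian_filter(o, sigma_px)
    return o / o.max()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
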