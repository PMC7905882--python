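"""Shared fixtures: deterministic masks and rendered spot images."""

import numpy as np
import pytest

from stedclust.core import StedImage
from stedclust.simulate import (
    GroundTruth,
    PointProcessSpec,
    RenderSpec,
    constant_fwhm_sampler,
    make_cell_mask,
)


@pytest.fixture(scope="session")
def mask192():
    """A fixed cell mask, 192x192 px at 20 nm pixels."""
    return make_cell_mask((192, 192), 20.0, seed=1)


@pytest.fixture(scope="session")
def render_noiseless():
    return RenderSpec(pixel_size=20.0, peak_photons=300.0, noise="none")


@pytest.fixture
def single_spot_factory(mask192):
    """Render one spot of a given FWHM at a given centre (nm)."""
    from stedclust.simulate import render_sted_image

    def make(fwhm=80.0, center=(1900.0, 1900.0), noise="none", peak=300.0, seed=0):
        gt = GroundTruth(
            true_points=np.array([center], dtype=float),
            true_fwhm=np.array([float(fwhm)]),
            process=PointProcessSpec(),
            seed=seed,
        )
        spec = RenderSpec(pixel_size=20.0, peak_photons=peak, noise=noise)
        return render_sted_image(gt, spec, mask192, seed), gt

    return make


@pytest.fixture
def grid_spots_image(mask192):
    """Well-separated bright spots on a jittered grid inside the mask.

    Returns (image, true_points): every pair of spots is >= 300 nm
    apart, suitable for recall/precision checks.
    """
    from scipy import ndimage

    rng = np.random.default_rng(42)
    px = mask192.pixel_size
    interior = ndimage.binary_erosion(mask192.mask, iterations=8)  # >=160 nm inside
    dist_ok = type(mask192)(mask=interior, pixel_size=px)
    pts = []
    for gx in range(2, 10):
        for gy in range(2, 10):
            p = np.array([gx * 400.0, gy * 400.0]) + rng.uniform(-40, 40, 2)
            if dist_ok.contains(p[None])[0]:
                pts.append(p)
    pts = np.array(pts)
    gt = GroundTruth(
        true_points=pts,
        true_fwhm=np.full(len(pts), 70.0),
        process=PointProcessSpec(),
        seed=0,
    )
    spec = RenderSpec(
        pixel_size=px,
        peak_photons=300.0,
        noise="poisson",
        spot_fwhm=constant_fwhm_sampler(70.0),
    )
    from stedclust.simulate import render_sted_image

    return render_sted_image(gt, spec, mask192, seed=7), pts


@pytest.fixture
def blank_image():
    """A 96x96 zero image at 20 nm pixels (valid but featureless)."""
    return StedImage(pixels=np.zeros((96, 96)), pixel_size=20.0)
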