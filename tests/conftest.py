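"""Shared fixtures: small phantoms and simple geometric images.

Unit tests run on a half-scale phantom canvas (300x600) for speed; the
end-to-end acceptance tests use the full default geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from zebreg.io_core import Raster
from zebreg.phantom import PhantomSpec, make_reference, make_target

SMALL_CANVAS = (300, 600)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(canvas=SMALL_CANVAS, deform_scale=5.0, seed=11)


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return make_reference(small_spec)


@pytest.fixture(scope="session")
def small_target(small_spec, small_reference):
    return make_target(small_reference, small_spec)


@pytest.fixture(scope="session")
def ellipse_image() -> tuple[Raster, np.ndarray]:
    """Bright axis-aligned ellipse (semi-axes 100 x 30) on black, noiseless."""
    rr, cc = np.mgrid[0:300, 0:500]
    inside = ((rr - 150) / 30.0) ** 2 + ((cc - 250) / 100.0) ** 2 <= 1.0
    img = np.where(inside, 200.0, 0.0)
    return Raster(img), inside


def random_blob_mask(rng: np.random.Generator, shape=(80, 120)) -> np.ndarray:
    """A random smooth blob for property tests (possibly empty)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=8)
    return field > np.quantile(field, 0.8)
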