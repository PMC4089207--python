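import numpy as np
import pytest

from ultraspeckle import (GrayImage, classify_field, compute_eigensystem,
                          default_phantom_spec, hessian_field, make_phantom,
                          normalize_field)


@pytest.fixture(scope="session")
def phantom():
    """The standard 256x256 test phantom with its ground-truth mask."""
    return make_phantom(default_phantom_spec(seed=0))


@pytest.fixture(scope="session")
def phantom_classified(phantom):
    """Tensor field, responses, and raw structure map of the clean phantom."""
    img, truth = phantom
    tf = hessian_field(img)
    compute_eigensystem(tf)
    normalize_field(tf)
    rmaps, smap = classify_field(tf)
    return tf, rmaps, smap


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def straight_ridge(nrows=64, ncols=96, row=32, amplitude=90.0, width=1.8,
                   background=100.0):
    """A horizontal bright ridge with Gaussian cross-section on a flat field."""
    rr = np.arange(nrows, dtype=float)[:, None]
    img = background + amplitude * np.exp(
        -((rr - row) ** 2) / (2.0 * width**2)
    ) * np.ones((1, ncols))
    return GrayImage(np.clip(img, 0, 255))
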