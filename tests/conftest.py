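"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest

from hepajac.grids import Grid3D, LabelGrid
from hepajac.phantom import generate_anatomy


@pytest.fixture(scope="session")
def small_anatomy():
    """One deterministic phantom at coarse desk resolution."""
    return generate_anatomy(3, shape=(48, 48, 36), spacing=(4.0, 4.0, 5.0))


@pytest.fixture(scope="session")
def sphere_mask():
    """Digital sphere of radius 25 mm on a 2 mm lattice."""
    sp = (2.0, 2.0, 2.0)
    shape = (40, 40, 40)
    pt = np.stack(
        np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, sp)), indexing="ij"), axis=-1
    )
    mask = ((pt - 40.0) ** 2).sum(-1) < 25.0**2
    return LabelGrid(mask.astype(np.int32), sp)


@pytest.fixture
def ramp_grid():
    """Linear ramp f(x) = x_mm along the first axis."""
    vals = np.broadcast_to(
        (np.arange(20) * 2.0)[:, None, None], (20, 16, 12)
    ).astype(float).copy()
    return Grid3D(vals, spacing=(2.0, 3.0, 4.0))
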