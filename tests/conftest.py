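import numpy as np
import pytest

from hsipix.core_io import Hypercube


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_cube(rng):
    """Small random cube with a ragged foreground mask."""
    def make(rows=6, cols=7, bands=5, with_mask=True, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        data = r.random((rows, cols, bands))
        mask = r.random((rows, cols)) > 0.3 if with_mask else None
        if mask is not None and not mask.any():
            mask[rows // 2, cols // 2] = True
        wl = 900.0 + 5.0 * np.arange(bands)
        return Hypercube(data=data, wavelengths=wl, mask=mask)
    return make
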