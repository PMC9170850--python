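import numpy as np
import pytest

import amaquant as aq


@pytest.fixture(scope="session")
def std_phantom():
    """The standard study phantom: aneurysm, vertebra, blood pool, 4-mm blur, noise."""
    spec = aq.PhantomSpec(seed=1)
    pet, ct, line, truth = aq.make_phantom(spec)
    return spec, pet, ct, line, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Same geometry with no blur and no noise: pre-blur truth is directly visible."""
    spec = aq.PhantomSpec(psf_sigma_mm=0.0, noise_sd=0.0)
    pet, ct, line, truth = aq.make_phantom(spec)
    return spec, pet, ct, line, truth


@pytest.fixture
def unit_grid():
    """Factory for small grids filled with zeros."""

    def make(shape=(24, 24, 24), spacing=1.0, origin=(0.0, 0.0, 0.0), fill=0.0):
        if np.isscalar(spacing):
            spacing = (spacing,) * 3
        return aq.ScalarVolume(np.full(shape, float(fill)), spacing, origin)

    return make
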