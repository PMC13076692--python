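"""Shared fixtures: the default digital phantom and its simulated scans.

Session-scoped because phantom generation and the forward blur on the full
128^3 grid cost ~1 s each and many tests reuse them read-only.
"""

import numpy as np
import pytest

from spectpvc.core import PSFModel
from spectpvc.phantom import (
    NoiseModel,
    PhantomSpec,
    generate_phantom,
    simulate_reconstruction,
)

ADOPTED_SIGMA_MM = 6.0


@pytest.fixture(scope="session")
def phantom():
    """Default digital NEMA phantom: (spec, truth, sphere_vois, bkg_vois)."""
    spec = PhantomSpec()
    truth, sphere_vois, bkg_vois = generate_phantom(spec)
    return spec, truth, sphere_vois, bkg_vois


@pytest.fixture(scope="session")
def blurred_phantom(phantom):
    """Noiseless simulated reconstruction at the adopted sigma (6.0 mm)."""
    _, truth, _, _ = phantom
    return simulate_reconstruction(truth, PSFModel(ADOPTED_SIGMA_MM))


@pytest.fixture(scope="session")
def noisy_phantom(phantom):
    """Simulated reconstruction with the default Poisson noise model."""
    _, truth, _, _ = phantom
    return simulate_reconstruction(
        truth, PSFModel(ADOPTED_SIGMA_MM), NoiseModel(seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
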